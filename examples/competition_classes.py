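"""Classify competitors of an effector/GTPase association.

Premixing a dark competitor with the effector suppresses the association
amplitude if binding is mutually exclusive.  Kinetics, not affinity,
decides: a competitor with decent affinity but a slow on-rate cannot
intercept the GTPase before the effector does.
"""

from rhoselect import MixConfig, RateConstants, competition_outcome

effector = RateConstants(kon=1.0, koff=0.5)  # Kd 0.5 uM
competitors = {
    "fast & tight (CRIB-domain-like)": RateConstants(kon=50.0, koff=0.001),
    "moderate (GEF/GAP-like)": RateConstants(kon=0.6, koff=0.05),
    "slow despite Kd 2.7 uM": RateConstants(kon=0.005, koff=0.0135),
}
for name, rates in competitors.items():
    out = competition_outcome(effector, rates, MixConfig(C0=20.0))
    print(f"{name:32s} amplitude ratio {out.amplitude_ratio:6.3f} "
          f"-> {out.competition_class}")
print("\nratio = association amplitude with/without 10x competitor excess; "
      ">=0.8 not affected, <=0.1 complete block.")
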