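"""From an elution profile to a complex stoichiometry call.

Simulates a gel-filtration run of an effector/GTPase complex on a 24-mL
column (void 8 mL), calibrates Kav vs log10(mass), infers the apparent
mass of the detected peak and asks which integer composition of the two
components explains it.
"""

from rhoselect import (detect_peaks, fit_calibration, infer_mass,
                       infer_stoichiometry, kav)
from rhoselect.sec import GPPNHP_MASS_KDA, synthetic_calibration_standards
from rhoselect.synthetic import generate_elution_profile

cal = fit_calibration(synthetic_calibration_standards())
# a ~228 kDa species elutes near 11.6 mL on this calibration
profile = generate_elution_profile([(11.6, 1.0, 0.25)], noise=0.005, seed=2)
(peak,) = detect_peaks(profile, min_height=0.2)
mass = infer_mass(peak.elution_volume, cal)

effector_kda, gtpase_kda = 91.0, 19.5 + GPPNHP_MASS_KDA
st = infer_stoichiometry(mass, effector_kda, gtpase_kda)

print(f"peak at {peak.elution_volume:.2f} mL, "
      f"Kav {kav(peak.elution_volume):.4f}, apparent mass {mass:.0f} kDa")
print(f"best composition: {st.copies[0]} x {effector_kda} kDa + "
      f"{st.copies[1]} x {gtpase_kda} kDa = {st.predicted_mass:.1f} kDa "
      f"(|error| {st.error:.1f} kDa)")
print("A ~228 kDa species of these components is a 2:2 heterotetramer.")
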