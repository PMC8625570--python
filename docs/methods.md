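# Methods

`rhoselect` bundles the computational analyses used to establish which
RHO-family GTPases an IQGAP scaffold binds, and why: kinetic inference
from stopped-flow traces, discrimination of specificity-determining
sequence positions, electrostatic (net-charge) summaries, size-exclusion
stoichiometry, and structural interface mapping. This note records the
models, their assumptions, the defaults and the reasoning behind the
genuinely open design choices.

## Binding kinetics

**Model.** Effector binding is a single reversible bimolecular step,
R + E ⇌ RE, with association rate constant kon (µM⁻¹ s⁻¹), dissociation
rate constant koff (s⁻¹) and Kd = koff/kon (µM). All schemes are
mass-action ODE systems integrated with a stiff-capable solver (LSODA,
rtol 1e-8, atol 1e-12); rate constants across the fixture table span four
orders of magnitude. Signals are normalised complex occupancy ([RE]/R0)
on an arbitrary fluorescence scale; the instrument dead time (2 ms) is
truncated from every trace.

**Association.** Under pseudo-first-order (PFO) conditions, E0 ≥ 5·R0,
the simulated trace is the closed-form exponential
`a + b(1 − exp(−kobs t))` with kobs = kon·E0 + koff — precisely the model
the downstream single-exponential fit assumes, which is also how the
laboratory protocol analyses such traces. Below that excess the full
system is integrated and a warning flags that a single-exponential
analysis is approximate. Separately, `association_closed_form` provides
the exact analytic solution of the reversible second-order rate equation
(via the equilibrium quadratic); the test suite requires the numerical
integrator to agree with it to 1e-4 relative. Note the distinction: the
PFO exponential is an approximation whose error is of order R0/E0
(percent-level at 10× excess); the analytic solution is exact.

**Displacement.** The preformed labeled complex (equilibrated at R0/E0)
is mixed with U0 = 10 µM of unlabeled protein that captures free
effector. Capture is modeled one-way by default (re-release to the
scarce labeled species is negligible at the excess used; a reversible
displacer is available and demonstrably accelerates the apparent decay,
approaching koff only as U0 grows). Two systematic effects remain even
so: an initial burst while the displacer absorbs the free-effector pool,
and a late-time competitive-rebinding bias as labeled GTPase accumulates.
The analysis therefore excludes the first 3/(kon·U0) seconds and fits
about three half-lives of the remaining decay. The single-exponential
displacement readout is only a valid koff estimator when capture is much
faster than complex decay; the estimation protocol checks that
kon·U0 ≥ 20·koff and otherwise falls back to the kobs-series intercept
(see below), with a warning.

**Full estimation protocol.** Association traces at 2, 4, 6 and 8 µM
effector are each fitted with a single exponential; kobs versus E0 is fit
by ordinary least squares, whose slope is kon and whose intercept is a
koff estimate. One displacement trace gives a direct koff. The direct
value is authoritative when the displacement experiment is valid (it is
far less noise-sensitive than the extrapolated intercept, which for tight
binders is a small difference of large numbers and is clamped at zero
when negative); for weak/fast-dissociating species the intercept is both
exact in the noiseless limit and relatively precise, and is used instead.
Kd = koff/kon, reported in nM below 1 µM. Replicates over seeds yield
means ± sd and the intercept-vs-direct discrepancy is always reported.

**Competition.** Premixed effector (signal) and competitor (dark) bind
the GTPase mutually exclusively: R + E ⇌ RE, R + C ⇌ RC; the premixed
proteins do not interact with each other. The observed association
amplitude is the peak signal above the start — robust to the
rise-then-fall shape produced by a slow, tight competitor. The outcome
ratio ρ = amplitude(with)/amplitude(without competitor) is classified
not_affected (ρ ≥ 0.8), partial, or complete (ρ ≤ 0.1); the numeric
thresholds are package conventions (the underlying assay is qualitative)
and the raw ρ is always reported. ρ is monotone non-increasing in both
competitor concentration and competitor kon; competition is kinetic, not
thermodynamic — a competitor of equal affinity but slow on-rate does not
interfere.

**Regulator assays.** GAP-stimulated hydrolysis is pseudo-first-order
(k_gap) on free GTPase only; effector-bound GTPase is protected, so the
observed rate falls monotonically with effector concentration and, under
rapid equilibrium, approaches k_gap·Kd/(Kd + E0) — half the bare rate at
E0 = Kd. GEF-catalyzed fluorescent-GDP release proceeds at k_gef and is
untouched by an effector that binds only the triphosphate form.

**Noise model.** Additive iid Gaussian noise, standard deviation given as
a fraction of the full signal span, from a seeded generator. Replicate
sub-seeds derive deterministically from the replicate seed. Real
instrument records also contain drift, photobleaching, mixing artifacts
and correlated noise; none are modeled, so parameter-recovery results
demonstrate correctness of the estimators under the stated noise model,
not robustness to instrument pathology.

**Exponential fitting.** Nonlinear least squares (trust-region, kobs
bounded positive). Initial kobs from the time to reach half the observed
span; offset/amplitude from the first/last deciles. Constant traces and
non-convergence raise a fit error with diagnostics. kobs is invariant
under affine transformations of the signal.

## The ground-truth fixture table

Fixture entries anchor the dissociation constants and ratios that define
the study conditions: Kd('rac2') = 27 nM; Kd('rac1') = 34 × Kd('rac2')
(the 34-fold ratio is taken as authoritative and split 4.25× slower kon /
8× faster koff); Kd('cdc42') = Kd('rac1')/3; 'grd_cdc42q61l' = 2.37 µM;
the four hotspot-swap variants of rac1 lose 7–17-fold affinity with
slower association and faster dissociation. Absolute kon values are
package choices within the typical effector range (0.5–10 µM⁻¹s⁻¹), noted
as such in each entry's provenance string. Nonbinder entries carry a
vanishing affinity (Kd ≈ 5 mM) so association screens show no signal
rather than raising errors.

## Hotspot discovery

A labeled multiple alignment (binders vs nonbinders, reference-numbered)
is scanned column by column. For each column with a reference residue:
f_b is the binder consensus frequency (ties broken alphabetically for
deterministic reports) and d the fraction of nonbinders whose residue
falls in a different physicochemical class than the binder consensus
(classes: hydrophobic ACFGILMPVW, polar HNQSTY, positive KR, negative DE;
gaps are a distinct symbol — never conserved, always deviating; columns
where the reference is gapped are skipped because they have no reference
name). A column is a candidate when f_b ≥ 0.8, d ≥ 0.6, and its
reference position lies outside the excluded regions (defaults: the
switch I/II effector-binding regions, residues 29–42 and 62–68, which are
nearly identical across the family and carry no selectivity
information). Candidates are grouped left-to-right into sites while
consecutive positions are ≤ 7 apart. Class-level rather than strict
residue deviation implements "clearly deviate": a nonbinder carrying a
chemically equivalent residue is not evidence of specificity. The
thresholds are explicit, configurable, and echoed in every report; no
significance testing (entropy or mutual-information p-values) is
attempted.

## Sequence statistics

*Net charge*: q = (#K + #R) − (#D + #E) over the record or a stated
domain interval; histidine is not counted (the convention names only
D/E/R/K). Charges are in elementary units at the sequence level — no pKa
or structure correction. *Percent identity*: global alignment with
BLOSUM62, gap open 10, gap extension 0.5; identity = identical aligned
pairs / alignment columns excluding terminal-gap columns, so a fragment
aligned to a longer construct is not penalised for the overhang. Results
are conventionally reported to the nearest integer. *Molecular mass*:
sum of average residue masses plus one water, kDa to three decimals; a
bound GppNHp nucleotide adds 0.52 kDa where complexes are mass-modeled.
*Variants*: substitutions are expressed in full-length numbering and the
stated wild-type residue is verified against the sequence, which catches
numbering-offset mistakes loudly.

## Size-exclusion chromatography

Kav = (Ve − V0)/(Vc − V0) on a column with void volume 8 mL and geometric
volume 24 mL (defaults). Calibration fits Kav against log10(mass) by
least squares over ≥ 3 standards and must have a negative slope. A
synthetic calibration standard set (13.7–669 kDa, a typical
gel-filtration kit, placed on an ideal line) ships for tests and demos —
clearly synthetic; real columns must be calibrated with real standards.
Peaks are local maxima with a three-point parabolic apex refinement.
Stoichiometry search enumerates copy numbers a, b ∈ [1, 4] minimising
|a·m1 + b·m2 − observed|, requiring both components present (the use case
is a peak whose gel shows both partners); ties break toward fewer total
copies, then fewer copies of the first component. The contract is the
nearest integer composition, not mass equality — apparent SEC masses
routinely deviate a few percent from sequence sums. No hydrodynamic
shape corrections and no deconvolution of overlapping peaks.

## Structure interface mapping

PDB input (HETATM skipped unless requested, first altloc kept, insertion
codes rejected, author numbering preserved). A residue is interfacial
when any of its heavy atoms (element ≠ H; crystal structures mostly lack
hydrogens) lies within 4.5 Å of any heavy atom of the partner chain
group; distances exactly at the cutoff count. Hotspot positions are
classified interface / proximal (≤ 8 Å) / distal, with unresolved for
residues absent from the model. Both cutoffs are flags: they are
conventional contact and near-contact distances, not values asserted from
any particular study. Neighbor search uses a k-d tree and is tested for
exact agreement with the all-pairs computation. No solvent-accessible
surface-area interface definition, no electrostatic potential maps, no
superposition/RMSD.

## Synthetic data: what it does and does not emulate

The generators produce seeded, deterministic stand-ins for every input:
PFO fluorescence traces with Gaussian noise, competition/GAP/GEF schemes,
toy labeled alignments with planted discriminating columns (background
identical everywhere else, optional per-row variable columns), Gaussian
elution profiles on a 0.02-mL grid, and two-chain toy complexes with an
exact engineered contact count. They establish that the estimators and
detectors are correct on data obeying their assumptions. They do not
emulate: real sequence divergence (toy alignments have no phylogenetic
structure, so perfect planted-site recovery does not bound false-positive
rates on real alignments), instrument drift or photophysics, asymmetric
or tailing SEC peaks, or crystallographic disorder.

## Problem sizes and runtime

Defaults keep everything desk-scale: 200-point traces, four association
concentrations plus one displacement per replicate, five replicates for
noisy estimates, 1000-instance brute-force cross-checks, 500-atom
interface oracles. The full test suite runs in a few seconds; the
acceptance script in well under a minute.

## Known limitations

* Real accession-based inputs (UniProt sequences, alignments, crystal
  structures) are user-supplied files; the package never downloads.
  Checks that require them report exactly what is missing.
* The displacement koff carries a small residual bias (≲ 1%) from
  competitive rebinding even within its validity regime; the
  intercept-vs-direct discrepancy is reported so the disagreement is
  visible rather than silent.
* Per-trace single-exponential fitting plus linear regression mirrors the
  laboratory analysis; no global multi-trace fit of the raw scheme is
  attempted, so parameter correlations are not propagated.
* Competition classification thresholds (0.8/0.1) are conventions over a
  continuous ρ; borderline competitors legitimately move between classes
  with concentration.
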