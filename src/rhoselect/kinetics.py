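"""Stopped-flow binding kinetics: simulation and rate-constant inference.

The experimental design mirrored here is the classic fluorescence
stopped-flow protocol for effector/GTPase binding:

* association — a fluorescently labeled, GTP-analog-loaded GTPase (R, low
  concentration) is rapidly mixed with excess effector (E); the observed
  single-exponential rate obeys ``kobs = kon*[E]0 + koff`` under
  pseudo-first-order conditions, so a linear fit of kobs against effector
  concentration yields the association rate constant (slope) and an
  intercept estimate of the dissociation rate constant;
* displacement — the preformed labeled complex is mixed with a large excess
  of unlabeled protein that scavenges the free effector, making the signal
  decay report the dissociation rate constant directly;
* competition — effector and a dark competitor are premixed and rapidly
  mixed with the labeled GTPase; if binding is mutually exclusive, the
  competitor suppresses the association amplitude;
* regulator assays — GAP-driven hydrolysis of the fluorescent GTP analog is
  only possible on the free GTPase (an effector-bound GTPase is protected),
  while GEF-driven nucleotide release is untouched by an effector that only
  binds the triphosphate form.

All schemes are simulated as mass-action ODE systems (scipy, stiff-capable
LSODA, rtol 1e-8); association under pseudo-first-order excess (E0 >= 5 R0)
is generated from the closed-form exponential that the fitting model
assumes.  Units: concentrations in µM, time in s, kon in 1/(µM s), koff in
1/s, Kd = koff/kon in µM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import curve_fit

from .errors import FitError, ValidationError

RTOL = 1e-8
ATOL = 1e-12


@dataclass(frozen=True)
class RateConstants:
    """Bimolecular association/dissociation rate constants."""

    kon: float   # 1/(µM s)
    koff: float  # 1/s

    def __post_init__(self):
        if self.kon <= 0:
            raise ValidationError(f"kon must be > 0 (got {self.kon})")
        if self.koff < 0:
            raise ValidationError(f"koff must be >= 0 (got {self.koff})")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant in µM."""
        return self.koff / self.kon


@dataclass
class MixConfig:
    """Post-mixing concentrations and acquisition settings.

    Defaults follow the standard protocol: 0.2 µM labeled GTPase mixed with
    2 µM effector; 20 µM premixed competitor (10-fold molar excess over the
    effector); 10 µM unlabeled displacer; 2 ms instrument dead time.
    """

    R0: float = 0.2        # µM labeled GTPase
    E0: float = 2.0        # µM effector
    C0: float = 20.0       # µM competitor
    U0: float = 10.0       # µM unlabeled displacer
    dead_time: float = 0.002  # s
    duration: Optional[float] = None  # s; None -> chosen per experiment
    n_points: int = 200

    def __post_init__(self):
        for name in ("R0", "E0", "C0", "U0"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_points < 10:
            raise ValidationError("n_points must be >= 10")
        if self.duration is not None and self.duration <= self.dead_time:
            raise ValidationError("duration must exceed the dead time")


@dataclass
class Trace:
    """A time course of fluorescence signal (arbitrary units)."""

    times: np.ndarray
    signal: np.ndarray
    sigma: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.times.shape != self.signal.shape:
            raise ValidationError("times and signal must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")

    def to_tsv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.signal]),
                   delimiter="\t", header="time_s\tsignal", comments="")

    @classmethod
    def from_tsv(cls, path) -> "Trace":
        data = np.loadtxt(path, delimiter="\t", skiprows=1)
        return cls(times=data[:, 0], signal=data[:, 1])


@dataclass(frozen=True)
class ExpFit:
    """Single-exponential fit result: a + b(1-e^(-kt)) or a + b e^(-kt)."""

    offset: float
    amplitude: float
    kobs: float
    rms: float
    kobs_stderr: float
    direction: str  # 'rising' or 'falling'


@dataclass(frozen=True)
class SeriesFit:
    """Linear kobs-vs-concentration fit: slope = kon, intercept = koff."""

    pairs: tuple
    kon: float
    koff: float
    r_squared: float


@dataclass(frozen=True)
class CompetitionOutcome:
    """Amplitude/rate ratios (with vs without competitor) and a class."""

    amplitude_ratio: float
    kobs_ratio: Optional[float]
    competition_class: str  # not_affected | partial | complete


# ---------------------------------------------------------------------------
# helpers


def _times(mix: MixConfig, duration: float) -> np.ndarray:
    end = mix.duration if mix.duration is not None else duration
    if end <= mix.dead_time:
        end = mix.dead_time * 10
    return np.linspace(mix.dead_time, end, mix.n_points)


def _add_noise(signal: np.ndarray, sigma: float, seed: Optional[int],
               span: float = 1.0) -> np.ndarray:
    if sigma <= 0:
        return signal
    rng = np.random.default_rng(seed)
    return signal + rng.normal(0.0, sigma * span, size=signal.shape)


def binding_equilibrium(rates: RateConstants, R0: float, E0: float) -> float:
    """Equilibrium complex concentration of R + E <-> RE (exact quadratic)."""
    if R0 == 0 or E0 == 0:
        return 0.0
    b = R0 + E0 + rates.kd
    return (b - np.sqrt(b * b - 4 * R0 * E0)) / 2


def association_closed_form(rates: RateConstants, R0: float, E0: float,
                            t: np.ndarray) -> np.ndarray:
    """Exact complex concentration [RE](t) for reversible R + E <-> RE.

    This is the analytic solution of the full second-order mass-action rate
    equation (no pseudo-first-order approximation), starting from [RE] = 0.
    """
    if R0 == 0 or E0 == 0:
        return np.zeros_like(t)
    b = R0 + E0 + rates.kd
    disc = np.sqrt(b * b - 4 * R0 * E0)
    x1, x2 = (b - disc) / 2, (b + disc) / 2
    lam = rates.kon * (x2 - x1)
    e = np.exp(-lam * np.asarray(t))
    return x1 * x2 * (1 - e) / (x2 - x1 * e)


def integrate_association(rates: RateConstants, R0: float, E0: float,
                          t: np.ndarray) -> dict:
    """Numerically integrate R + E <-> RE; returns species concentrations."""

    def rhs(_, y):
        r, e, x = y
        v = rates.kon * r * e - rates.koff * x
        return [-v, -v, v]

    sol = solve_ivp(rhs, (0.0, float(t[-1])), [R0, E0, 0.0], t_eval=t,
                    method="LSODA", rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise FitError(f"association integration failed: {sol.message}")
    return {"R": sol.y[0], "E": sol.y[1], "RE": sol.y[2]}


# ---------------------------------------------------------------------------
# simulators


def simulate_association(rates: RateConstants, mix: MixConfig | None = None,
                         sigma: float = 0.0, seed: Optional[int] = None,
                         method: str = "auto", baseline: float = 0.0,
                         span: float = 1.0, return_species: bool = False):
    """Simulate an association trace (signal proportional to [RE]/R0).

    Under pseudo-first-order conditions (E0 >= 5 R0) the trace is the
    closed-form exponential with ``kobs = kon*E0 + koff`` — the model the
    downstream fit assumes.  Below that excess the full mass-action system
    is integrated and a warning notes that a single-exponential analysis is
    approximate.  ``method`` forces ``'pfo'``, ``'ode'`` or
    ``'closed_form'`` (exact analytic solution) if needed.
    """
    mix = mix or MixConfig()
    if mix.R0 <= 0:
        raise ValidationError("R0 must be > 0 for an association experiment")
    if mix.E0 < 0:
        raise ValidationError("E0 must be >= 0")
    kobs = rates.kon * mix.E0 + rates.koff
    t = _times(mix, duration=5.0 / kobs if kobs > 0 else 1.0)
    species = None
    if mix.E0 == 0:
        x = np.zeros_like(t)
    elif method == "pfo" or (method == "auto" and mix.E0 >= 5 * mix.R0):
        amp = mix.R0 * mix.E0 / (mix.E0 + rates.kd)
        x = amp * (1 - np.exp(-kobs * t))
    elif method == "closed_form":
        x = association_closed_form(rates, mix.R0, mix.E0, t)
    else:
        if method == "auto":
            warnings.warn(
                f"E0 = {mix.E0} µM is below 5x R0 = {mix.R0} µM: "
                "pseudo-first-order conditions violated; integrating the "
                "full mass-action system", stacklevel=2)
        species = integrate_association(rates, mix.R0, mix.E0, t)
        x = species["RE"]
    signal = baseline + span * x / mix.R0
    trace = Trace(t, _add_noise(signal, sigma, seed, span), sigma, seed)
    return (trace, species) if return_species else trace


def simulate_displacement(rates: RateConstants, mix: MixConfig | None = None,
                          sigma: float = 0.0, seed: Optional[int] = None,
                          displacer_rates: RateConstants | None = None,
                          baseline: float = 0.0, span: float = 1.0,
                          return_species: bool = False):
    """Simulate effector displacement from the preformed labeled complex.

    The labeled complex (R*E, equilibrated at R0/E0) is mixed with an
    excess of unlabeled protein U that captures the free effector.  By
    default the capture is treated as one-way (the displacer's own
    re-release to the scarce labeled species is negligible at the excess
    used); pass ``displacer_rates`` to model a reversible displacer.  The
    falling signal reports koff; at finite U0 a small rebinding bias
    remains because the labeled GTPase competes for released effector.
    """
    mix = mix or MixConfig()
    urates = displacer_rates or RateConstants(kon=rates.kon, koff=0.0)
    if mix.U0 < 10 * mix.R0:
        warnings.warn(
            f"U0 = {mix.U0} µM is below the 10x R0 excess expected for a "
            "displacement experiment; fitted rate will underestimate koff",
            stacklevel=2)
    x0 = binding_equilibrium(rates, mix.R0, mix.E0)
    t = _times(mix, duration=5.0 / rates.koff if rates.koff > 0 else 1.0)

    def rhs(_, y):
        x, r, e, u, ue = y
        v1 = rates.kon * r * e - rates.koff * x
        v2 = urates.kon * u * e - urates.koff * ue
        return [v1, -v1, -v1 - v2, -v2, v2]

    y0 = [x0, mix.R0 - x0, mix.E0 - x0, mix.U0, 0.0]
    sol = solve_ivp(rhs, (0.0, float(t[-1])), y0, t_eval=t, method="LSODA",
                    rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise FitError(f"displacement integration failed: {sol.message}")
    species = {"RE": sol.y[0], "R": sol.y[1], "E": sol.y[2],
               "U": sol.y[3], "UE": sol.y[4]}
    signal = baseline + span * species["RE"] / mix.R0
    trace = Trace(t, _add_noise(signal, sigma, seed, span), sigma, seed)
    return (trace, species) if return_species else trace


def simulate_competition(rates_effector: RateConstants,
                         rates_competitor: RateConstants,
                         mix: MixConfig | None = None, sigma: float = 0.0,
                         seed: Optional[int] = None, baseline: float = 0.0,
                         span: float = 1.0, return_species: bool = False):
    """Simulate association in the presence of a premixed dark competitor.

    Effector (signal-generating) and competitor bind the GTPase mutually
    exclusively: R + E <-> RE and R + C <-> RC; only [RE] contributes to
    the signal.  With C0 = 0 this reduces to a plain association trace.
    """
    mix = mix or MixConfig()
    if mix.C0 == 0:
        return simulate_association(rates_effector, mix, sigma, seed,
                                    baseline=baseline, span=span,
                                    return_species=return_species)
    if mix.R0 <= 0 or mix.E0 <= 0:
        raise ValidationError("R0 and E0 must be > 0 for competition")
    kobs = rates_effector.kon * mix.E0 + rates_effector.koff
    t = _times(mix, duration=5.0 / kobs)

    def rhs(_, y):
        r, e, c, x, yc = y
        v1 = rates_effector.kon * r * e - rates_effector.koff * x
        v2 = rates_competitor.kon * r * c - rates_competitor.koff * yc
        return [-v1 - v2, -v1, -v2, v1, v2]

    sol = solve_ivp(rhs, (0.0, float(t[-1])), [mix.R0, mix.E0, mix.C0, 0, 0],
                    t_eval=t, method="LSODA", rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise FitError(f"competition integration failed: {sol.message}")
    species = {"R": sol.y[0], "E": sol.y[1], "C": sol.y[2],
               "RE": sol.y[3], "RC": sol.y[4]}
    signal = baseline + span * species["RE"] / mix.R0
    trace = Trace(t, _add_noise(signal, sigma, seed, span), sigma, seed)
    return (trace, species) if return_species else trace


def simulate_gap_reaction(rates_effector: RateConstants, k_gap: float,
                          mix: MixConfig | None = None, sigma: float = 0.0,
                          seed: Optional[int] = None, baseline: float = 0.0,
                          span: float = 1.0, return_species: bool = False):
    """Simulate GAP-stimulated hydrolysis with effector protection.

    Free GTP-loaded GTPase loses its fluorescent nucleotide signal at the
    pseudo-first-order rate ``k_gap``; the effector-bound fraction is
    protected.  The falling signal tracks the remaining unhydrolyzed
    GTPase, [R] + [RE].  With effective effector binding the observed rate
    tends to ``k_gap * Kd / (Kd + E0)`` (rapid-equilibrium limit).
    """
    mix = mix or MixConfig()
    if k_gap <= 0:
        raise ValidationError("k_gap must be > 0")
    x0 = binding_equilibrium(rates_effector, mix.R0, mix.E0)
    free_frac = rates_effector.kd / (rates_effector.kd + mix.E0) \
        if mix.E0 > 0 else 1.0
    t = _times(mix, duration=5.0 / (k_gap * max(free_frac, 1e-3)))

    def rhs(_, y):
        g, x = y
        e = mix.E0 - x
        v = rates_effector.kon * g * e - rates_effector.koff * x
        return [-k_gap * g - v, v]

    sol = solve_ivp(rhs, (0.0, float(t[-1])), [mix.R0 - x0, x0], t_eval=t,
                    method="LSODA", rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise FitError(f"GAP reaction integration failed: {sol.message}")
    species = {"R": sol.y[0], "RE": sol.y[1]}
    signal = baseline + span * (species["R"] + species["RE"]) / mix.R0
    trace = Trace(t, _add_noise(signal, sigma, seed, span), sigma, seed)
    return (trace, species) if return_species else trace


def simulate_gef_reaction(k_gef: float,
                          effector_rates: RateConstants | None = None,
                          binds_gdp_form: bool = False,
                          mix: MixConfig | None = None, sigma: float = 0.0,
                          seed: Optional[int] = None, baseline: float = 0.0,
                          span: float = 1.0):
    """Simulate GEF-catalyzed fluorescent-GDP release.

    The signal decays single-exponentially at ``k_gef``.  An effector that
    binds only the triphosphate form leaves the exchange reaction untouched
    (it never sees the GDP-loaded substrate); a hypothetical GDP-form
    binder sequesters substrate and slows the observed release.
    """
    mix = mix or MixConfig()
    if k_gef <= 0:
        raise ValidationError("k_gef must be > 0")
    t = _times(mix, duration=5.0 / k_gef)
    if effector_rates is None or not binds_gdp_form or mix.E0 == 0:
        signal = baseline + span * np.exp(-k_gef * t)
        return Trace(t, _add_noise(signal, sigma, seed, span), sigma, seed)

    x0 = binding_equilibrium(effector_rates, mix.R0, mix.E0)

    def rhs(_, y):
        d, de = y
        e = mix.E0 - de
        v = effector_rates.kon * d * e - effector_rates.koff * de
        return [-k_gef * d - v, v]

    sol = solve_ivp(rhs, (0.0, float(t[-1])), [mix.R0 - x0, x0], t_eval=t,
                    method="LSODA", rtol=RTOL, atol=ATOL)
    if not sol.success:
        raise FitError(f"GEF reaction integration failed: {sol.message}")
    signal = baseline + span * (sol.y[0] + sol.y[1]) / mix.R0
    return Trace(t, _add_noise(signal, sigma, seed, span), sigma, seed)


# ---------------------------------------------------------------------------
# fitting


def fit_single_exponential(trace: Trace, direction: str = "auto") -> ExpFit:
    """Nonlinear least-squares single-exponential fit of a trace.

    Rising model: ``a + b(1 - exp(-kobs t))``; falling: ``a + b exp(-kobs
    t)``.  Initial kobs comes from the time to reach half the observed
    span; offset/amplitude from the first/last deciles.
    """
    t, y = trace.times, trace.signal
    if len(t) < 10:
        raise FitError("need at least 10 points for an exponential fit")
    span = float(np.ptp(y))
    scale = max(abs(float(np.max(np.abs(y)))), 1.0)
    if span == 0 or span < 1e-9 * scale:
        raise FitError("constant trace: no exponential to fit")
    n10 = max(len(t) // 10, 1)
    first, last = float(np.mean(y[:n10])), float(np.mean(y[-n10:]))
    if direction == "auto":
        direction = "rising" if last > first else "falling"
    mid = (first + last) / 2
    cross = np.nonzero((y >= mid) if direction == "rising" else (y <= mid))[0]
    t_half = t[cross[0]] - t[0] if len(cross) else (t[-1] - t[0]) / 2
    k0 = np.log(2) / max(t_half, (t[1] - t[0]))

    if direction == "rising":
        def model(tt, a, b, k):
            return a + b * (1 - np.exp(-k * tt))
        p0 = [first, last - first, k0]
    else:
        def model(tt, a, b, k):
            return a + b * np.exp(-k * tt)
        p0 = [last, first - last, k0]

    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=20000,
                               bounds=([-np.inf, -np.inf, 1e-12],
                                       [np.inf, np.inf, np.inf]))
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    resid = y - model(t, *popt)
    stderr = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    return ExpFit(offset=float(popt[0]), amplitude=float(popt[1]),
                  kobs=float(popt[2]), rms=float(np.sqrt(np.mean(resid ** 2))),
                  kobs_stderr=stderr, direction=direction)


def fit_kobs_series(pairs: Sequence[tuple[float, float]]) -> SeriesFit:
    """Linear fit of kobs vs effector concentration: slope kon, intercept koff."""
    conc = np.array([p[0] for p in pairs], dtype=float)
    kobs = np.array([p[1] for p in pairs], dtype=float)
    if len(set(conc.tolist())) < 3:
        raise ValidationError("need kobs at >= 3 distinct concentrations")
    slope, intercept = np.polyfit(conc, kobs, 1)
    pred = slope * conc + intercept
    ss_res = float(np.sum((kobs - pred) ** 2))
    ss_tot = float(np.sum((kobs - np.mean(kobs)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope <= 0:
        warnings.warn("non-positive slope: no concentration-dependent "
                      "association detected (kon set to 0)", stacklevel=2)
        slope = 0.0
    if intercept < 0:
        warnings.warn(f"negative intercept {intercept:.3g} clamped to 0 "
                      "(noise-sensitive koff estimate)", stacklevel=2)
        intercept = 0.0
    return SeriesFit(pairs=tuple(pairs), kon=float(slope),
                     koff=float(intercept), r_squared=r2)


def compute_kd(rates: RateConstants) -> float:
    """Kd = koff/kon in µM."""
    return rates.koff / rates.kon


def format_kd(kd_um: float) -> str:
    """Human-readable Kd: nM below 1 µM, µM otherwise."""
    if kd_um < 1.0:
        return f"{kd_um * 1e3:.3g} nM"
    return f"{kd_um:.3g} µM"


def classify_competition(amplitude_ratio: float,
                         kobs_ratio: Optional[float] = None,
                         not_affected_above: float = 0.8,
                         complete_below: float = 0.1) -> CompetitionOutcome:
    """Classify a competition outcome from the amplitude ratio ρ.

    ρ >= 0.8 -> not_affected; ρ <= 0.1 -> complete; otherwise partial.  The
    numeric thresholds are package conventions reported alongside the raw
    ratio (qualitative classes in the underlying assay).
    """
    if amplitude_ratio < 0:
        raise ValidationError("amplitude ratio must be >= 0")
    if amplitude_ratio >= not_affected_above:
        klass = "not_affected"
    elif amplitude_ratio <= complete_below:
        klass = "complete"
    else:
        klass = "partial"
    return CompetitionOutcome(amplitude_ratio, kobs_ratio, klass)


def competition_outcome(rates_effector: RateConstants,
                        rates_competitor: RateConstants,
                        mix: MixConfig | None = None, sigma: float = 0.0,
                        seed: Optional[int] = None) -> CompetitionOutcome:
    """Run paired with/without-competitor simulations and classify the effect."""
    mix = mix or MixConfig()
    from dataclasses import replace as dc_replace
    mix0 = dc_replace(mix, C0=0.0)
    base = simulate_competition(rates_effector, rates_competitor, mix0,
                                sigma, seed)
    comp = simulate_competition(rates_effector, rates_competitor, mix,
                                sigma, seed)

    def _amp_k(trace):
        # observed association amplitude: peak above the starting signal
        # (robust to the rise-then-fall shape a slow tight competitor
        # produces); kobs from a fit of the rising segment where possible
        sig = trace.signal
        i_max = int(np.argmax(sig))
        amp = float(sig[i_max] - sig[0])
        k = None
        try:
            seg = trace if i_max < 10 else Trace(trace.times[:i_max + 1],
                                                 sig[:i_max + 1],
                                                 trace.sigma, trace.seed)
            k = fit_single_exponential(seg, "rising").kobs
        except FitError:
            pass
        return max(amp, 0.0), k

    amp0, k0 = _amp_k(base)
    amp1, k1 = _amp_k(comp)
    if amp0 == 0:
        raise ValidationError("zero baseline amplitude: nothing to compete with")
    ratio = amp1 / amp0
    kratio = (k1 / k0) if (k0 and k1) else None
    return classify_competition(ratio, kratio)


# ---------------------------------------------------------------------------
# full estimation protocol


@dataclass(frozen=True)
class EstimationResult:
    """kon/koff/Kd recovered by the association-series + displacement protocol."""

    kon: float
    kon_sd: float
    koff_direct: float
    koff_direct_sd: float
    koff_intercept: float
    koff_intercept_sd: float
    kd: float       # µM, authoritative koff / kon
    kd_sd: float
    n_replicates: int
    koff_source: str = "displacement"  # which estimate Kd is based on

    @property
    def koff_discrepancy(self) -> float:
        """Relative difference between displacement and intercept koff."""
        if self.koff_direct == 0:
            return 0.0
        return abs(self.koff_direct - self.koff_intercept) / self.koff_direct


def estimate_from_traces(association: Sequence[tuple[float, Trace]],
                         displacement: Trace,
                         displacer_conc: float | None = None
                         ) -> tuple[SeriesFit, ExpFit]:
    """Fit each association trace and the displacement trace.

    ``association`` pairs each trace with its effector concentration (µM).
    When ``displacer_conc`` (U0, µM) is given, the first 3/(kon·U0)
    seconds of the displacement trace — the burst phase in which the
    displacer captures the free-effector pool — are excluded before the
    single-exponential fit, using the kon just measured from the series.
    Returns the kobs-vs-concentration series fit and the displacement fit.
    """
    pairs = [(conc, fit_single_exponential(tr, "rising").kobs)
             for conc, tr in association]
    series = fit_kobs_series(pairs)
    disp_trace = displacement
    if displacer_conc and series.kon > 0:
        t_burst = 3.0 / (series.kon * displacer_conc)
        disp_trace = _window(displacement, t_burst, None)
    disp = fit_single_exponential(disp_trace, "falling")
    if disp_trace is not displacement:
        # second pass: fit over ~3 half-lives after the burst; the long
        # plateau adds no rate information but accrues rebinding bias
        t0 = disp_trace.times[0]
        disp_trace2 = _window(disp_trace, 0.0, 3 * np.log(2) / disp.kobs)
        if disp_trace2 is not disp_trace:
            disp = fit_single_exponential(disp_trace2, "falling")
    return series, disp


def _window(trace: Trace, t_start_offset: float,
            length: float | None) -> Trace:
    """Sub-trace from t0+offset spanning ``length`` seconds (>=10 points)."""
    t0 = trace.times[0]
    keep = trace.times >= t0 + t_start_offset
    if length is not None:
        keep &= trace.times <= t0 + t_start_offset + length
    if keep.sum() < 10 or keep.all():
        return trace
    return Trace(trace.times[keep], trace.signal[keep], trace.sigma,
                 trace.seed)


def run_full_estimation(rates_or_name, sigma: float = 0.0,
                        seeds: Sequence[int] = (0,),
                        concentrations: Sequence[float] = (2.0, 4.0, 6.0, 8.0),
                        mix: MixConfig | None = None) -> EstimationResult:
    """The complete protocol: association series + displacement, replicated.

    For each seed, association traces at the given effector concentrations
    and one displacement trace are simulated, fitted, and reduced to kon
    (series slope) and koff.  The displacement-derived koff is
    authoritative whenever the displacement experiment is valid — effector
    capture (kon*U0) at least 20x faster than complex decay — because the
    series intercept is noise-sensitive; outside that regime the
    single-exponential displacement readout is biased and the intercept is
    used instead (with a warning).  Kd = koff/kon.  Results are means
    (± sd) over seeds; the intercept-vs-direct discrepancy is reported.
    """
    if isinstance(rates_or_name, str):
        from .synthetic import make_kinetics_fixture
        rates = make_kinetics_fixture()[rates_or_name].rates
    else:
        rates = rates_or_name
    mix = mix or MixConfig()
    from dataclasses import replace as dc_replace

    kons, koffs_d, koffs_i, kds, sources = [], [], [], [], []
    for seed in seeds:
        assoc = []
        for i, conc in enumerate(concentrations):
            sub = (seed * 1009 + i) % (2 ** 31) if seed is not None else None
            m = dc_replace(mix, E0=float(conc), duration=None)
            assoc.append((conc, simulate_association(rates, m, sigma, sub)))
        sub = (seed * 1009 + 97) % (2 ** 31) if seed is not None else None
        disp = simulate_displacement(rates, dc_replace(mix, duration=None),
                                     sigma, sub)
        series, dfit = estimate_from_traces(assoc, disp,
                                            displacer_conc=mix.U0)
        if series.kon == 0:
            raise FitError("no association detected: kon slope is zero")
        kons.append(series.kon)
        koffs_d.append(dfit.kobs)
        koffs_i.append(series.koff)
        separation = dfit.kobs / (series.kon * mix.U0) if mix.U0 > 0 else np.inf
        if separation <= 0.05:
            kds.append(dfit.kobs / series.kon)
            sources.append("displacement")
        else:
            warnings.warn(
                f"displacement capture only {1 / separation:.1f}x faster "
                "than dissociation: single-exponential displacement readout "
                "unreliable, using the series intercept for koff",
                stacklevel=2)
            kds.append(series.koff / series.kon)
            sources.append("intercept")

    def _ms(v):
        a = np.asarray(v)
        return float(a.mean()), float(a.std(ddof=1)) if len(a) > 1 else 0.0

    kon_m, kon_s = _ms(kons)
    kd_m, kd_s = _ms(kds)
    kde_m, kde_s = _ms(koffs_d)
    ki_m, ki_s = _ms(koffs_i)
    return EstimationResult(kon=kon_m, kon_sd=kon_s, koff_direct=kde_m,
                            koff_direct_sd=kde_s, koff_intercept=ki_m,
                            koff_intercept_sd=ki_s, kd=kd_m, kd_sd=kd_s,
                            n_replicates=len(seeds),
                            koff_source=max(set(sources), key=sources.count))
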