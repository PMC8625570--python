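"""Kinetics: simulators vs closed forms, exponential fits, full protocol."""

import numpy as np
import pytest

from rhoselect import (MixConfig, RateConstants, Trace,
                       association_closed_form, classify_competition,
                       competition_outcome, compute_kd, fit_kobs_series,
                       fit_single_exponential, format_kd,
                       run_full_estimation, simulate_association,
                       simulate_competition, simulate_displacement,
                       simulate_gap_reaction, simulate_gef_reaction)
from rhoselect.errors import FitError, ValidationError
from rhoselect.kinetics import integrate_association
from rhoselect.synthetic import make_kinetics_fixture

RATES = RateConstants(kon=1.0, koff=0.5)


class TestAssociation:
    def test_pseudo_first_order_kobs_recovered_exactly(self):
        trace = simulate_association(RATES, MixConfig(R0=0.2, E0=2.0))
        fit = fit_single_exponential(trace, "rising")
        assert fit.kobs == pytest.approx(2.5, rel=1e-6)

    def test_no_effector_flat_baseline(self):
        trace = simulate_association(RATES, MixConfig(E0=0.0, duration=1.0))
        assert np.allclose(trace.signal, 0.0)

    def test_low_excess_warns_and_deviates_from_pfo(self):
        mix = MixConfig(R0=0.2, E0=0.4, duration=3.0)
        with pytest.warns(UserWarning, match="pseudo-first-order"):
            trace = simulate_association(RATES, mix)
        kobs = RATES.kon * mix.E0 + RATES.koff
        amp = mix.R0 * mix.E0 / (mix.E0 + RATES.kd)
        pfo = amp * (1 - np.exp(-kobs * trace.times)) / mix.R0
        rel = np.max(np.abs(trace.signal - pfo)) / np.max(pfo)
        assert rel > 0.01

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValidationError):
            MixConfig(E0=-1.0)

    def test_integrator_matches_exact_solution_at_10x_excess(self):
        mix = MixConfig(R0=0.2, E0=2.0)
        t = np.linspace(0.002, 2.0, 300)
        exact = association_closed_form(RATES, mix.R0, mix.E0, t)
        numeric = integrate_association(RATES, mix.R0, mix.E0, t)["RE"]
        rel = np.max(np.abs(numeric - exact)) / np.max(exact)
        assert rel < 1e-4


class TestDisplacement:
    def test_koff_recovered_within_5_percent(self):
        rates = RateConstants(kon=8.0, koff=0.216)
        trace = simulate_displacement(rates, MixConfig())
        fit = fit_single_exponential(trace, "falling")
        assert fit.kobs == pytest.approx(0.216, rel=0.05)

    def test_zero_koff_flat(self):
        rates = RateConstants(kon=8.0, koff=0.0)
        trace = simulate_displacement(rates, MixConfig(duration=2.0))
        assert np.ptp(trace.signal) < 1e-9

    def test_reversible_displacer_bias_shrinks_with_excess(self):
        # with a reversible displacer the fitted rate sits above koff and
        # approaches it as the displacer excess grows
        rates = RateConstants(kon=8.0, koff=0.216)
        fitted = []
        for u0 in (10.0, 30.0, 100.0):
            tr = simulate_displacement(rates, MixConfig(U0=u0),
                                       displacer_rates=rates)
            fitted.append(fit_single_exponential(tr, "falling").kobs)
        assert fitted[0] > fitted[1] > fitted[2] > rates.koff
        assert abs(fitted[2] - rates.koff) < abs(fitted[0] - rates.koff)

    def test_low_excess_warns(self):
        with pytest.warns(UserWarning, match="excess"):
            simulate_displacement(RATES, MixConfig(U0=1.0))


class TestCompetition:
    def test_no_competitor_equals_association(self):
        mix = MixConfig(C0=0.0)
        a = simulate_association(RATES, mix)
        c = simulate_competition(RATES, RateConstants(50.0, 0.001), mix)
        assert np.array_equal(a.signal, c.signal)

    def test_fast_tight_competitor_abolishes_binding(self):
        out = competition_outcome(RATES, RateConstants(kon=50.0, koff=0.001),
                                  MixConfig(C0=20.0))
        assert out.amplitude_ratio < 0.1
        assert out.competition_class == "complete"

    def test_slow_competitor_has_no_effect(self):
        # Kd 2.7 µM but very slow on-rate: cannot intercept the GTPase
        out = competition_outcome(RATES, RateConstants(kon=0.005,
                                                       koff=0.0135),
                                  MixConfig(C0=20.0))
        assert out.amplitude_ratio > 0.8
        assert out.competition_class == "not_affected"

    def test_amplitude_monotone_in_competitor_concentration(self):
        comp = RateConstants(kon=2.0, koff=0.1)
        ratios = [competition_outcome(RATES, comp,
                                      MixConfig(C0=c)).amplitude_ratio
                  for c in (0.0, 5.0, 20.0, 60.0)]
        assert all(a >= b - 1e-9 for a, b in zip(ratios, ratios[1:]))

    def test_amplitude_monotone_in_competitor_kon(self):
        ratios = [competition_outcome(RATES, RateConstants(kon=k, koff=0.1),
                                      MixConfig(C0=20.0)).amplitude_ratio
                  for k in (0.01, 0.3, 3.0, 30.0)]
        assert all(a >= b - 1e-9 for a, b in zip(ratios, ratios[1:]))

    def test_mass_conservation_in_integrator(self):
        mix = MixConfig(R0=0.2, E0=2.0, C0=20.0)
        _, sp = simulate_competition(RATES, RateConstants(2.0, 0.1), mix,
                                     return_species=True)
        total = sp["R"] + sp["RE"] + sp["RC"]
        assert np.max(np.abs(total - mix.R0)) < 1e-8


class TestRegulatorAssays:
    def test_gap_rate_without_effector(self):
        trace = simulate_gap_reaction(RATES, k_gap=0.8, mix=MixConfig(E0=0.0))
        fit = fit_single_exponential(trace, "falling")
        assert fit.kobs == pytest.approx(0.8, rel=1e-3)

    def test_gap_protection_monotone_in_effector(self):
        rates = RateConstants(kon=10.0, koff=10.0)  # Kd 1 µM, fast equil
        obs = []
        for e0 in (0.0, 0.5, 1.0, 4.0, 20.0):
            tr = simulate_gap_reaction(rates, k_gap=0.05,
                                       mix=MixConfig(E0=e0))
            obs.append(fit_single_exponential(tr, "falling").kobs)
        assert all(a > b for a, b in zip(obs, obs[1:]))

    def test_gap_half_rate_at_kd(self):
        rates = RateConstants(kon=10.0, koff=10.0)  # Kd = 1 µM
        tr = simulate_gap_reaction(rates, k_gap=0.05, mix=MixConfig(E0=1.0))
        fit = fit_single_exponential(tr, "falling")
        assert fit.kobs == pytest.approx(0.025, rel=0.10)

    def test_gef_rate_bare(self):
        tr = simulate_gef_reaction(k_gef=0.6)
        assert fit_single_exponential(tr, "falling").kobs == pytest.approx(
            0.6, rel=1e-6)

    def test_gef_untouched_by_triphosphate_only_effector(self):
        bare = simulate_gef_reaction(k_gef=0.6)
        with_eff = simulate_gef_reaction(k_gef=0.6, effector_rates=RATES,
                                         binds_gdp_form=False)
        k0 = fit_single_exponential(bare, "falling").kobs
        k1 = fit_single_exponential(with_eff, "falling").kobs
        assert k1 == pytest.approx(k0, rel=0.01)

    def test_gef_slowed_by_gdp_form_binder(self):
        slow = simulate_gef_reaction(k_gef=0.6,
                                     effector_rates=RateConstants(10.0, 1.0),
                                     binds_gdp_form=True)
        k = fit_single_exponential(slow, "falling").kobs
        assert k < 0.5 * 0.6


class TestExponentialFit:
    def test_constant_trace_rejected(self):
        t = np.linspace(0, 1, 50)
        with pytest.raises(FitError, match="constant"):
            fit_single_exponential(Trace(t, np.ones_like(t)))

    def test_affine_invariance_of_kobs(self):
        trace = simulate_association(RATES, MixConfig())
        k0 = fit_single_exponential(trace).kobs
        scaled = Trace(trace.times, 7.5 * trace.signal - 3.0)
        assert fit_single_exponential(scaled).kobs == pytest.approx(
            k0, rel=1e-9)

    def test_noisy_replicates_unbiased(self):
        true_kobs = 2.5
        estimates, errors = [], []
        for seed in range(100):
            tr = simulate_association(RATES, MixConfig(), sigma=0.02,
                                      seed=seed)
            f = fit_single_exponential(tr, "rising")
            estimates.append(f.kobs)
            errors.append(f.kobs_stderr)
        mean = np.mean(estimates)
        sem = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(mean - true_kobs) < 3 * sem
        # reported per-fit standard errors in the right ballpark
        assert np.median(errors) == pytest.approx(np.std(estimates, ddof=1),
                                                  rel=0.5)


class TestSeriesFit:
    def test_exact_line(self):
        fit = fit_kobs_series([(2, 2.5), (4, 4.5), (6, 6.5), (8, 8.5)])
        assert fit.kon == pytest.approx(1.0)
        assert fit.koff == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)

    def test_flat_series_warns_kon_zero(self):
        with pytest.warns(UserWarning, match="no concentration-dependent"):
            fit = fit_kobs_series([(2, 1.0), (4, 1.0), (6, 1.0)])
        assert fit.kon == 0.0

    def test_too_few_concentrations(self):
        with pytest.raises(ValidationError):
            fit_kobs_series([(2, 2.5), (4, 4.5)])

    def test_negative_intercept_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            fit = fit_kobs_series([(2, 1.9), (4, 4.1), (6, 5.9)])
        assert fit.koff == 0.0

    def test_noisy_series_recovery(self):
        rng = np.random.default_rng(3)
        pairs = [(c, 1.0 * c + 0.5 + rng.normal(0, 0.05))
                 for c in (2, 4, 6, 8)]
        fit = fit_kobs_series(pairs)
        assert fit.kon == pytest.approx(1.0, rel=0.10)


class TestKd:
    def test_simple_ratio(self):
        assert compute_kd(RateConstants(1.0, 0.5)) == pytest.approx(0.5)

    def test_nanomolar_formatting(self):
        kd = compute_kd(RateConstants(8.0, 0.216))
        assert kd == pytest.approx(0.027)
        assert format_kd(kd) == "27 nM"

    def test_zero_koff(self):
        assert compute_kd(RateConstants(1.0, 0.0)) == 0.0


class TestClassification:
    @pytest.mark.parametrize("rho,klass", [
        (1.0, "not_affected"), (0.8, "not_affected"), (0.5, "partial"),
        (0.1, "complete"), (0.05, "complete")])
    def test_thresholds(self, rho, klass):
        assert classify_competition(rho).competition_class == klass

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValidationError):
            classify_competition(-0.1)


class TestFullEstimation:
    def test_noiseless_recovery_all_binder_fixtures(self):
        table = make_kinetics_fixture()
        for name, entry in table.items():
            if not entry.binder:
                continue
            res = run_full_estimation(name)
            assert res.kon == pytest.approx(entry.rates.kon, rel=0.01), name
            assert res.kd == pytest.approx(entry.kd, rel=0.01), name

    def test_noisy_recovery_highest_affinity_entry(self):
        res = run_full_estimation("rac2", sigma=0.02, seeds=[1, 2, 3, 4, 5])
        assert res.kd == pytest.approx(0.027, rel=0.15)
        assert res.n_replicates == 5

    def test_koff_discrepancy_reported(self):
        res = run_full_estimation("rac2")
        assert res.koff_discrepancy < 0.05
        assert res.koff_source == "displacement"

    def test_screen_dichotomy_binders_vs_nonbinders(self):
        # the association screen: binder fixtures give a clear signal
        # amplitude, vanishing-affinity nonbinders essentially none
        table = make_kinetics_fixture()
        for name, entry in table.items():
            trace = simulate_association(entry.rates, MixConfig(E0=8.0))
            amp = float(np.ptp(trace.signal))
            if entry.binder:
                assert amp > 0.25, name
            else:
                assert amp < 0.01, name
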