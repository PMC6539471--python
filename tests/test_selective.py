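"""T1 fitting, decay correction, window selection and rate arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hpkinetics import (
    AcquisitionScheme,
    DegenerateModelError,
    KineticParams,
    NoPlateauError,
    T1DecayModel,
    aggregate_rates,
    correct_precursor_eq2,
    fit_t1_eq1,
    generate_continuous_flow,
    rate_eq3,
    select_constant_window,
)


def _decay(t, m0, t1, angle, tr):
    return m0 * np.exp(-t / t1) * np.cos(np.deg2rad(angle)) ** (t / tr)


def _sel_scheme(tr=8.0, angle=5.0, n=12):
    return AcquisitionScheme(tr=tr, nutation_precursor=angle,
                             nutation_product=90.0, n_samples=n)


class TestT1Fit:
    def test_pure_exponential_recovery(self):
        """theta = 0 reduces the decay law to a plain exponential."""
        scheme = _sel_scheme(angle=0.0)
        t = scheme.times
        est = fit_t1_eq1(t, _decay(t, 1.0, 53.4, 0.0, 8.0), scheme)
        assert est.t1 == pytest.approx(53.4, rel=1e-6)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)

    def test_recovery_with_rf_losses(self):
        scheme = _sel_scheme(tr=8.0, angle=5.0, n=10)
        t = scheme.times
        est = fit_t1_eq1(t, _decay(t, 2.5, 50.0, 5.0, 8.0), scheme)
        assert est.t1 == pytest.approx(50.0, rel=1e-6)
        assert est.m0 == pytest.approx(2.5, rel=1e-6)
        assert est.r2 == pytest.approx(1.0, abs=1e-12)

    def test_rf_only_decay_yields_huge_t1(self):
        """When all decay comes from pulsation the fitted T1 diverges."""
        scheme = _sel_scheme(tr=8.0, angle=5.0, n=10)
        t = scheme.times
        est = fit_t1_eq1(t, _decay(t, 1.0, 1e9, 5.0, 8.0), scheme)
        assert est.t1 >= 1e6

    def test_90_degree_readout_is_degenerate(self):
        scheme = AcquisitionScheme(tr=8.0, nutation_precursor=90.0,
                                   nutation_product=90.0, n_samples=10)
        with pytest.raises(DegenerateModelError):
            fit_t1_eq1(scheme.times, np.ones(10), scheme)

    def test_estimator_interface(self):
        est = T1DecayModel(tr=8.0, nutation=5.0)
        est.set_params(**est.get_params())
        t = np.arange(10) * 8.0
        y = _decay(t, 1.0, 40.0, 5.0, 8.0)
        est.fit(t, y)
        np.testing.assert_allclose(est.predict(t), y, rtol=1e-8)


class TestDecayCorrection:
    def test_roundtrip_constancy(self):
        """Correcting a series generated by the decay law gives a constant."""
        scheme = _sel_scheme(tr=8.0, angle=5.0, n=10)
        t = scheme.times
        y = _decay(t, 3.7, 53.4, 5.0, 8.0)
        cor = correct_precursor_eq2(t, y, 53.4, scheme=scheme)
        np.testing.assert_allclose(cor.corrected, 3.7, rtol=1e-9)

    def test_t1_only_correction_flag(self):
        scheme = _sel_scheme(tr=8.0, angle=5.0, n=10)
        t = scheme.times
        y = np.exp(-t / 53.4)
        cor = correct_precursor_eq2(t, y, 53.4, scheme=scheme, include_rf=False)
        np.testing.assert_allclose(cor.corrected, 1.0, rtol=1e-12)

    def test_amplification_ceiling_flags_late_points(self):
        t = np.array([0.0, 10.0, 200.0])
        cor = correct_precursor_eq2(t, np.exp(-t / 50.0), 50.0, max_amplification=20.0)
        assert list(cor.unreliable) == [False, False, True]


class TestWindowSelection:
    def test_constant_series_selects_all(self):
        w = select_constant_window(np.full(6, 5.0))
        assert list(w) == [0, 1, 2, 3, 4, 5]

    def test_ten_percent_rule_from_first_maximum(self):
        """Points within 10% of the first maximum, stopping at the first
        violation: [100, 99, 95, 91, 89, 60] -> {0, 1, 2, 3}."""
        w = select_constant_window(np.array([100.0, 99, 95, 91, 89, 60]))
        assert list(w) == [0, 1, 2, 3]

    def test_noise_spike_guard(self):
        """A one-point spike early on is not mistaken for the maximum."""
        v = np.array([50.0, 100.0, 98.0, 99.0, 97.0, 40.0])
        w = select_constant_window(v)
        assert w[0] == 1
        assert list(w) == [1, 2, 3, 4]

    def test_washout_tail_excluded(self):
        v = np.array([100.0, 98.0, 97.0, 80.0, 60.0, 40.0])
        assert list(select_constant_window(v)) == [0, 1, 2]

    def test_too_few_points(self):
        with pytest.raises(NoPlateauError):
            select_constant_window(np.array([1.0, 2.0]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        plateau=st.integers(3, 12),
        drop=st.floats(0.2, 0.9),
        jitter=st.floats(0.0, 0.04),
        seed=st.integers(0, 1000),
    )
    def test_idempotence_on_plateau_decay_series(self, plateau, drop, jitter, seed):
        """Re-running selection on the windowed subset returns the same set."""
        rng = np.random.default_rng(seed)
        v = np.concatenate([
            np.full(plateau, 100.0) * (1 + jitter * rng.standard_normal(plateau)),
            100.0 * drop * np.exp(-np.arange(5) / 2.0),
        ])
        w1 = select_constant_window(v)
        if w1.size < 3:
            return
        w2 = select_constant_window(v[w1])
        assert list(w1[w2]) == list(w1)


class TestRateArithmetic:
    def test_worked_signal_ratio(self):
        """The study-scale worked example: ratio 1.987e-3 at TR = 12 s,
        14 mM x 0.5 mL, 11.4 nmole ATP -> ~6.1 nmole/min/nmole ATP."""
        v = rate_eq3(1.987e-3, 1.0, pyr_conc=14.0, rho=1.0, tr=12.0,
                     v_medium=0.5, atp=11.4)
        assert v == pytest.approx(6.1, abs=0.05)

    def test_zero_product_zero_rate(self):
        assert rate_eq3(0.0, 1.0, 14.0, 1.0, 12.0, 0.5, 11.4) == 0.0

    @pytest.mark.parametrize("factor", [2.0, 0.5, 10.0])
    def test_linearity_and_inverse_linearity(self, factor):
        base = rate_eq3(1e-3, 1.0, 14.0, 1.0, 12.0, 0.5, 11.4)
        assert rate_eq3(factor * 1e-3, 1.0, 14.0, 1.0, 12.0, 0.5, 11.4) == pytest.approx(factor * base)
        assert rate_eq3(1e-3, 1.0, 14.0, factor, 12.0, 0.5, 11.4) == pytest.approx(factor * base)
        assert rate_eq3(1e-3, 1.0, factor * 14.0, 1.0, 12.0, 0.5, 11.4) == pytest.approx(factor * base)
        assert rate_eq3(1e-3, 1.0, 14.0, 1.0, factor * 12.0, 0.5, 11.4) == pytest.approx(base / factor)
        assert rate_eq3(1e-3, 1.0, 14.0, 1.0, 12.0, 0.5, factor * 11.4) == pytest.approx(base / factor)

    def test_noise_floor_exclusion(self):
        v = rate_eq3(np.array([1e-3, 1e-3]), np.array([1.0, 1e-9]),
                     14.0, 1.0, 12.0, 0.5, 11.4, noise_floor=1e-6)
        assert np.isfinite(v[0]) and np.isnan(v[1])

    def test_aggregate_uses_upper_plateau(self):
        rates = np.array([2.0, 4.0, 5.0, 5.1, 4.9, 5.0])
        agg = aggregate_rates(rates, plateau_tol=0.15)
        assert list(agg.stabilized_indices) == [2, 3, 4, 5]
        assert agg.mean_rate == pytest.approx(np.mean(rates[2:]))
        assert agg.sd_rate == pytest.approx(np.std(rates[2:], ddof=1))


class TestFlowChain:
    """Corrected continuous-flow series: plateau, window and rate recovery."""

    PARAMS = KineticParams(k1st=1.6e-4, t1_precursor=53.4, t1_product=20.0, m0=1.0)
    SCHEME = AcquisitionScheme.selective(tr=8.0, precursor_nutation=5.0, n_samples=40)

    def test_corrected_plateau_matches_generator_amplitude(self):
        series, truth = generate_continuous_flow(self.PARAMS, self.SCHEME)
        cor = correct_precursor_eq2(series.times, series.precursor,
                                    truth["t1_precursor"], scheme=self.SCHEME)
        steady_end = truth["arrival_time"] + truth["buildup_duration"] + truth["steady_duration"]
        sel = (series.times >= truth["steady_onset"] + 40.0) & (series.times <= steady_end)
        plateau_mean = np.mean(cor.corrected[sel])
        assert plateau_mean == pytest.approx(truth["steady_amplitude"], rel=0.01)

    def test_window_starts_near_steady_onset(self):
        series, truth = generate_continuous_flow(self.PARAMS, self.SCHEME)
        cor = correct_precursor_eq2(series.times, series.precursor,
                                    truth["t1_precursor"], scheme=self.SCHEME)
        w = select_constant_window(cor)
        assert abs(series.times[w[0]] - truth["steady_onset"]) <= 2 * self.SCHEME.tr

    def test_end_to_end_rate_recovery_under_noise(self):
        """Full chain at per-channel SNR 50 recovers the generator's
        plateau rate within 10%."""
        clean, truth = generate_continuous_flow(self.PARAMS, self.SCHEME)
        rng = np.random.default_rng(7)
        atp = 11.4
        means = []
        for _ in range(5):
            noisy_p = clean.precursor + rng.normal(0, clean.precursor.max() / 50, len(clean))
            noisy_l = clean.product + rng.normal(0, clean.product.max() / 50, len(clean))
            cor = correct_precursor_eq2(clean.times, noisy_p,
                                        truth["t1_precursor"], scheme=self.SCHEME)
            w = select_constant_window(cor)
            rho = np.sin(np.deg2rad(self.SCHEME.nutation_precursor))
            rates = rate_eq3(np.clip(noisy_l[w], 0, None), noisy_p[w],
                             truth["pyr_conc_mm"], rho, self.SCHEME.tr,
                             truth["v_medium_ml"], atp)
            means.append(aggregate_rates(rates).mean_rate)
        expected = truth["expected_rate_nmole_per_min"] / atp
        assert np.mean(means) == pytest.approx(expected, rel=0.10)
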