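"""Synthetic generators: determinism, model consistency, truth recovery."""

import numpy as np
import pytest

from hpkinetics import (
    AcquisitionScheme,
    KineticParams,
    NoiseModel,
    fit_two_pool,
    generate_arrest_nonselective,
    generate_arrest_selective,
    generate_continuous_flow,
    generate_p31_pair,
    quantify_atp,
    simulate_two_pool,
)

PARAMS = KineticParams(k1st=1.55e-4, t1_precursor=64.5, t1_product=20.0, m0=1.0)


@pytest.mark.parametrize("generator,scheme", [
    (generate_arrest_nonselective, AcquisitionScheme.nonselective(n_samples=30)),
    (generate_arrest_selective, AcquisitionScheme.selective(n_samples=15)),
    (generate_continuous_flow, AcquisitionScheme.selective(n_samples=30)),
])
def test_fixed_seed_is_deterministic(generator, scheme):
    noise = NoiseModel(sigma=0.01, seed=42)
    s1, t1 = generator(PARAMS, scheme, noise=noise)
    s2, t2 = generator(PARAMS, scheme, noise=noise)
    np.testing.assert_array_equal(s1.precursor, s2.precursor)
    np.testing.assert_array_equal(s1.product, s2.product)
    assert t1["seed"] == t2["seed"] == 42


def test_noiseless_nonselective_reproduces_simulator():
    scheme = AcquisitionScheme.nonselective(n_samples=40)
    series, truth = generate_arrest_nonselective(PARAMS, scheme)
    ref = simulate_two_pool(PARAMS, scheme)
    np.testing.assert_array_equal(series.precursor, ref.precursor)
    np.testing.assert_array_equal(series.product, ref.product)
    assert truth["k1st"] == PARAMS.k1st


def test_nonselective_recovery_study():
    """Fitted rate constants over 50 noisy replicates centre on truth."""
    scheme = AcquisitionScheme.nonselective(n_samples=66)
    clean = simulate_two_pool(PARAMS, scheme)
    ks = []
    for seed in range(50):
        noise = NoiseModel(sigma=0.005 * clean.product.max(), seed=seed)
        series, _ = generate_arrest_nonselective(PARAMS, scheme, noise=noise)
        ks.append(fit_two_pool(series, scheme).params.k1st)
    assert np.median(ks) == pytest.approx(PARAMS.k1st, rel=0.05)


class TestArrestSelective:
    SCHEME = AcquisitionScheme.selective(tr=8.0, precursor_nutation=5.0, n_samples=10)

    def test_product_over_one_tr_equals_quadrature(self):
        """With negligible product relaxation, each selective readout equals
        k times the integrated precursor magnetization over the interval."""
        params = KineticParams(k1st=2e-4, t1_precursor=50.0, t1_product=1e12, m0=1.0)
        series, truth = generate_arrest_selective(
            params, self.SCHEME, n_quench=4, quench_tr=2.0)
        mask = truth["analysis_mask"]
        t = series.times[mask]
        # precursor magnetization after the pulse preceding each analysis sample
        cp = np.cos(np.deg2rad(5.0))
        n_prior = np.flatnonzero(mask)  # pulses before each analysis sample
        for j, (tj, npul) in enumerate(list(zip(t, n_prior))[1:3], start=1):
            t_prev = series.times[mask][j - 1]
            p_post = (np.exp(-t_prev / 50.0) * cp ** (n_prior[j - 1] + 1)
                      * np.exp(-truth["injection_delay"] / 50.0))
            integral = p_post * 50.0 * (1.0 - np.exp(-(tj - t_prev) / 50.0))
            assert series.product[mask][j] == pytest.approx(
                params.k1st * integral, rel=1e-6)

    def test_quench_block_resets_preaccumulated_product(self):
        """With a 30 s injection period, omitting the quench block leaves the
        product accumulated over those 30 s in the first analysis sample,
        whereas quenching resets it so the sample reads a single TR's worth."""
        with_q, truth_q = generate_arrest_selective(
            PARAMS, self.SCHEME, n_quench=4, injection_delay=30.0)
        no_q, truth_n = generate_arrest_selective(
            PARAMS, self.SCHEME, n_quench=0, injection_delay=30.0)
        first_q = with_q.product[truth_q["analysis_mask"]][0]
        first_n = no_q.product[truth_n["analysis_mask"]][0]
        assert first_n > 1.3 * first_q

    def test_quench_samples_flagged(self):
        series, truth = generate_arrest_selective(PARAMS, self.SCHEME, n_quench=4)
        assert truth["analysis_mask"].sum() == self.SCHEME.n_samples
        assert not truth["analysis_mask"][:4].any()


class TestContinuousFlow:
    def test_constant_inflow_degenerates_to_arrest(self):
        """Instant arrival, fast mixing and an endless steady phase give a
        constant-concentration series like the arrested design."""
        from hpkinetics import FlowProfile
        scheme = AcquisitionScheme.selective(tr=8.0, precursor_nutation=5.0, n_samples=8)
        flow = FlowProfile(arrival_time=0.0, buildup_duration=0.0,
                           steady_duration=1e9, washout_rate=1e3)
        series, truth = generate_continuous_flow(PARAMS, scheme, flow=flow)
        arrest, _ = generate_arrest_selective(
            PARAMS, scheme, n_quench=0, injection_delay=0.0)
        np.testing.assert_allclose(series.precursor, arrest.precursor, rtol=1e-6)
        np.testing.assert_allclose(series.product[1:], arrest.product[1:], rtol=1e-3)

    def test_truth_record_carries_expected_rate(self):
        scheme = AcquisitionScheme.selective(tr=8.0, precursor_nutation=5.0, n_samples=40)
        series, truth = generate_continuous_flow(PARAMS, scheme)
        direct = PARAMS.k1st * truth["pyr_conc_mm"] * truth["v_medium_ml"] * 1e3 * 60.0
        # observed plateau rate is below the instantaneous production rate
        # by the product T1 loss over TR, but within a factor of ~0.7-1
        assert 0.6 * direct < truth["expected_rate_nmole_per_min"] <= direct


class TestP31Pair:
    def test_noiseless_roundtrip(self):
        sample, std, truth = generate_p31_pair(11.4)
        q = quantify_atp(sample, std, truth["standard_amount_nmole"])
        assert q.atp_amount == pytest.approx(11.4, rel=1e-9)

    def test_seed_determinism(self):
        a = generate_p31_pair(11.4, noise=NoiseModel(sigma=0.05, seed=3))
        b = generate_p31_pair(11.4, noise=NoiseModel(sigma=0.05, seed=3))
        assert a[0].integral == b[0].integral
        assert a[1].integral == b[1].integral

    def test_recovery_bias_under_noise(self):
        """5% integral noise over 100 seeds: mean recovered amount within 2%."""
        recovered = []
        for seed in range(100):
            sample, std, truth = generate_p31_pair(
                11.4, noise=NoiseModel(sigma=0.05, seed=seed))
            recovered.append(
                quantify_atp(sample, std, truth["standard_amount_nmole"]).atp_amount)
        assert np.mean(recovered) == pytest.approx(11.4, rel=0.02)
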