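import numpy as np
import pytest

import bim
from bim.spectral import (band_integrate, band_measures, coherence,
                          directed_coherence, geweke_spectral,
                          parzen_truncation_lag, parzen_window,
                          spectral_pipeline, transfer_and_psd, wc_psd)


@pytest.fixture(scope="module")
def unidir_spec(unidir_model):
    return spectral_pipeline(unidir_model)


class TestTransferAndPSD:
    def test_white_noise_spectrum_is_flat_identity(self):
        model = bim.ARXModel(p=1, A=np.zeros((1, 2, 2)), Sigma_U=np.eye(2))
        spec = transfer_and_psd(model, 128)
        np.testing.assert_allclose(spec.P, np.tile(np.eye(2), (128, 1, 1)),
                                   atol=1e-12)

    def test_unidirectional_benchmark_target_spectrum(self, unidir_spec):
        np.testing.assert_allclose(unidir_spec.P[:, 1, 1].real, 2.0, atol=1e-10)
        np.testing.assert_allclose(np.abs(unidir_spec.H[:, 1, 0]), 1.0,
                                   atol=1e-12)

    def test_ar1_dc_gain(self):
        A = np.zeros((1, 2, 2))
        A[0, 0, 0] = 0.5
        spec = transfer_and_psd(bim.ARXModel(p=1, A=A, Sigma_U=np.eye(2)), 101)
        assert spec.P[0, 0, 0].real == pytest.approx(4.0, abs=1e-10)

    def test_hermitian_psd(self):
        rng = np.random.default_rng(0)
        spec = transfer_and_psd(bim.random_stable_model(rng), 128)
        np.testing.assert_allclose(spec.P, spec.P.conj().transpose(0, 2, 1),
                                   atol=1e-14)
        assert np.all(spec.P[:, 0, 0].real > 0)


class TestCoherence:
    def test_uncoupled_zero(self):
        A = np.zeros((1, 2, 2))
        A[0, 0, 0] = 0.5
        spec = transfer_and_psd(bim.ARXModel(p=1, A=A, Sigma_U=np.eye(2)), 128)
        coh2 = coherence(spec)
        assert np.max(coh2) < 1e-12
        assert np.max(np.abs(spec.f_td)) < 1e-12

    def test_unidirectional_benchmark_half(self, unidir_spec):
        np.testing.assert_allclose(unidir_spec.coh2, 0.5, atol=1e-10)
        np.testing.assert_allclose(unidir_spec.f_td, np.log(2), atol=1e-10)

    def test_near_deterministic_coupling_approaches_one(self):
        spec = spectral_pipeline(
            bim.benchmark_unidirectional(c=1.0, Sigma_U=np.diag([1, 1e-8])).model)
        assert np.min(spec.coh2) > 1 - 1e-6


class TestDirectedCoherence:
    def test_unidirectional_benchmark(self, unidir_spec):
        np.testing.assert_allclose(unidir_spec.dc2_12, 0.5, atol=1e-10)
        np.testing.assert_allclose(unidir_spec.dc2_21, 0.0, atol=1e-12)

    def test_symmetric_coherence_asymmetric_dc(self):
        spec = spectral_pipeline(bim.benchmark_physio(coupling_12=0.6).model)
        assert np.max(spec.dc2_12) > 0.05
        assert np.max(spec.dc2_21) < 1e-10

    def test_gc_dc_link_under_strict_causality(self):
        rng = np.random.default_rng(1)
        spec = spectral_pipeline(bim.random_stable_model(rng, p=2))
        np.testing.assert_allclose(spec.f_gc_12, -np.log1p(-spec.dc2_12),
                                   atol=1e-10)

    def test_correlated_innovations_warn(self):
        model = bim.ARXModel(p=1, A=np.zeros((1, 2, 2)),
                             Sigma_U=np.array([[1, 0.5], [0.5, 1.0]]))
        spec = transfer_and_psd(model, 128)
        with pytest.warns(UserWarning, match="not diagonal"):
            directed_coherence(spec, model)


class TestGewekeProfiles:
    def test_unidirectional_benchmark_flat_profiles(self, unidir_spec):
        np.testing.assert_allclose(unidir_spec.f_gc_12, np.log(2), atol=1e-10)
        np.testing.assert_allclose(unidir_spec.f_gc_21, 0.0, atol=1e-12)
        np.testing.assert_allclose(unidir_spec.f_ic, 0.0, atol=1e-10)

    def test_frequencywise_decomposition_exact(self):
        rng = np.random.default_rng(2)
        for i in range(10):
            model = bim.random_stable_model(rng, strictly_causal=bool(i % 2))
            s = spectral_pipeline(model)
            np.testing.assert_allclose(
                s.f_td, s.f_gc_12 + s.f_gc_21 + s.f_ic, atol=1e-10)

    def test_instantaneous_only_model_integrates_to_time_domain(self):
        model = bim.ARXModel(p=1, A=np.zeros((1, 2, 2)),
                             Sigma_U=np.array([[1, 0.5], [0.5, 1.0]]))
        s = transfer_and_psd(model, 1001)
        geweke_spectral(s, model)
        assert 2 * band_integrate(s, s.f_ic, (0, 0.5)) == pytest.approx(
            np.log(1 / 0.75), abs=1e-6)
        assert 2 * band_integrate(s, s.f_gc_12, (0, 0.5)) == pytest.approx(0, abs=1e-10)


class TestBandIntegration:
    def test_whole_band_recovers_transfer_entropy(self, unidir_spec):
        t12 = band_integrate(unidir_spec, unidir_spec.f_gc_12, (0, 0.5))
        assert t12 == pytest.approx(np.log(2) / 2, abs=1e-6)

    def test_zero_profile_integrates_to_zero(self, unidir_spec):
        z = np.zeros_like(unidir_spec.fgrid)
        assert band_integrate(unidir_spec, z, (0.1, 0.2)) == 0.0

    def test_band_additivity(self):
        spec = spectral_pipeline(bim.benchmark_physio(coupling_12=0.5).model)
        bands = [(0, 0.04), (0.04, 0.15), (0.15, 0.4), (0.4, 0.5)]
        whole = band_integrate(spec, spec.f_td, (0, 0.5))
        parts = sum(band_integrate(spec, spec.f_td, b) for b in bands)
        assert parts == pytest.approx(whole, abs=1e-9)

    def test_band_outside_nyquist_rejected(self, unidir_spec):
        with pytest.raises(ValueError, match="outside"):
            band_integrate(unidir_spec, unidir_spec.f_td, (0.1, 0.7))

    def test_band_measures_collects_all_four(self, unidir_spec):
        bm = band_measures(unidir_spec, (0, 0.5))
        assert bm.T_12 == pytest.approx(np.log(2) / 2, abs=1e-6)
        assert abs(bm.T_21) < 1e-10 and abs(bm.I_it) < 1e-9
        assert bm.I_mir == pytest.approx(np.log(2) / 2, abs=1e-6)


class TestWeightedCovariance:
    def test_white_noise_flat_near_unit(self):
        rng = np.random.default_rng(3)
        L = 8192
        x = rng.standard_normal(L)
        x -= x.mean()
        pair = bim.TimeSeriesPair(x, rng.standard_normal(L))
        spec = wc_psd(pair, 30)
        p11 = spec.P[:, 0, 0].real
        # Parzen-window variance: var(P) ~ 2 P^2 * 0.539 tau / L
        se = np.sqrt(2 * 0.539 * 30 / L)
        assert np.max(np.abs(p11 - 1)) < 4 * se
        assert np.min(p11) > -1e-12

    def test_two_sided_integral_equals_sample_variance(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(2048)
        x -= x.mean()
        y = rng.standard_normal(2048)
        pair = bim.TimeSeriesPair(x, y)
        spec = wc_psd(pair, 64)
        integral = 2 * band_integrate(spec, spec.P[:, 0, 0].real, (0, 0.5))
        assert integral == pytest.approx(x.var(ddof=0), abs=1e-8)

    def test_ar2_peak_location(self):
        spec_model = bim.benchmark_physio(coupling_12=0, rho1=0.9, f1=0.1)
        pair = bim.simulate_arx(
            bim.SimulationSpec(model=spec_model.model, L=8192, seed=5))
        spec = wc_psd(pair, 100)
        fpeak = spec.fgrid[np.argmax(spec.P[:, 0, 0].real)]
        assert abs(fpeak - 0.1) < 0.02

    def test_bad_truncation_rejected(self, independent_pair):
        with pytest.raises(ValueError):
            wc_psd(independent_pair, independent_pair.L + 5)


class TestParzen:
    def test_window_shape(self):
        k = np.arange(-10, 11)
        w = parzen_window(k, 10)
        assert w[10] == 1.0
        assert np.all(w >= 0) and np.all(w <= 1)
        np.testing.assert_allclose(w, w[::-1])

    def test_bandwidth_relation_worked_values(self):
        raw, lag = parzen_truncation_lag(25, 1)
        assert raw == pytest.approx(0.05092, abs=1e-5)
        assert lag == 1
        raw, lag = parzen_truncation_lag(1.273, 1)
        assert raw == pytest.approx(1.0)
        raw, lag = parzen_truncation_lag(0.1, 1)
        assert raw == pytest.approx(12.73) and lag == 13

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            parzen_truncation_lag(0.0)
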