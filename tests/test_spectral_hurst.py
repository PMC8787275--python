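import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractalbold import (
    LabelAtlas,
    PowerSpectrum,
    UniformTimeSeries,
    Volume4D,
    classical_hurst,
    classical_to_beta,
    estimate_hurst,
    fit_scaling,
    voxelwise_hurst,
    welch_psd,
)
from fractalbold.spectral_hurst import segment_length
from fractalbold.synthetic_data import PowerLawSpec, synthesize_power_law

from conftest import white_noise_series


class TestWelchPsd:
    def test_segment_length_eight_windows_half_overlap(self):
        # N = L + 7 * L/2  =>  L = 2N/9, floored
        assert segment_length(900) == 200
        assert segment_length(450) == 100
        # eight segments at step floor(L/2) always fit inside the series
        for n in [900, 901, 899, 700]:
            L = segment_length(n)
            step = L // 2
            assert (8 - 1) * step + L <= n

    def test_frequency_resolution_and_dc_exclusion(self):
        series = white_noise_series(0, n=900)
        spec = welch_psd(series)
        assert spec.frequencies[0] == pytest.approx(1.0 / 200.0)
        df = np.diff(spec.frequencies)
        assert np.allclose(df, df[0])
        assert spec.frequencies[-1] == pytest.approx(0.5)

    def test_parseval_white_noise(self):
        # integral of the one-sided PSD over (0, Nyquist] recovers the variance
        integrals = []
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(900)
            x /= x.std()
            spec = welch_psd(UniformTimeSeries(x, 1.0))
            df = spec.frequencies[1] - spec.frequencies[0]
            integrals.append(spec.power.sum() * df)
        assert np.mean(integrals) == pytest.approx(1.0, rel=0.10)

    def test_sinusoid_peak_localized(self):
        t = np.arange(900)
        series = UniformTimeSeries(np.sin(2 * np.pi * 0.1 * t), 1.0)
        spec = welch_psd(series)
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(0.1)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            welch_psd(UniformTimeSeries(np.ones(900), 1.0))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(UniformTimeSeries(np.random.default_rng(0).standard_normal(40), 1.0))


class TestFitScaling:
    def test_exact_power_law_recovered_to_machine_precision(self):
        f = np.linspace(0.005, 0.5, 100)
        for beta in [-0.5, 0.0, 0.7, 1.5, 2.3]:
            spec = PowerSpectrum(f, f ** (-beta))
            fit = fit_scaling(spec)
            assert fit.beta == pytest.approx(beta, abs=1e-10)
            assert fit.hurst_extended == pytest.approx((beta + 1) / 2, abs=1e-10)
            assert fit.r_squared == pytest.approx(1.0, abs=1e-10)
        assert fit_scaling(PowerSpectrum(f, f ** -1.5)).signal_class == "fBm"

    def test_flat_spectrum_zero_beta_zero_intercept(self):
        f = np.linspace(0.005, 0.5, 100)
        fit = fit_scaling(PowerSpectrum(f, np.ones_like(f)))
        assert fit.beta == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.signal_class == "fGn"

    def test_lower_band_edge_is_strict(self):
        # bins at exactly f_min stay out of the fit
        f = np.array([0.01, 0.02, 0.04, 0.08, 0.16, 0.32])
        p = f ** -1.0
        p[0] = 1e12  # would wreck the fit if included
        fit = fit_scaling(PowerSpectrum(f, p), f_min=0.01)
        assert fit.beta == pytest.approx(1.0, abs=1e-10)
        assert fit.n_freq_bins == 5

    def test_too_few_bins_rejected(self):
        f = np.array([0.02, 0.04, 0.08])
        with pytest.raises(ValueError, match="bins"):
            fit_scaling(PowerSpectrum(f, f ** -1.0))

    def test_nonpositive_bins_excluded(self):
        f = np.linspace(0.02, 0.5, 30)
        p = f ** -1.0
        p[5] = 0.0
        fit = fit_scaling(PowerSpectrum(f, p))
        assert fit.n_freq_bins == 29
        assert fit.beta == pytest.approx(1.0, abs=1e-10)


class TestEstimateHurst:
    def test_white_noise_hurst_near_half(self):
        estimates = [estimate_hurst(white_noise_series(seed)).hurst_extended
                     for seed in range(200)]
        assert np.mean(estimates) == pytest.approx(0.5, abs=0.02)

    def test_fgn_class_input(self):
        fits = [estimate_hurst(synthesize_power_law(
            PowerLawSpec(beta_target=0.5, n_samples=900, seed=s)))
            for s in range(50)]
        assert np.mean([f.hurst_extended for f in fits]) == pytest.approx(0.75, abs=0.05)
        assert sum(f.signal_class == "fGn" for f in fits) >= 45

    def test_fbm_class_input_has_hurst_above_one(self):
        fits = [estimate_hurst(synthesize_power_law(
            PowerLawSpec(beta_target=1.8, n_samples=900, seed=s)))
            for s in range(50)]
        assert all(f.hurst_extended > 1 for f in fits)
        assert all(f.signal_class == "fBm" for f in fits)

    def test_constant_series_is_an_error_not_h_zero(self):
        with pytest.raises(ValueError):
            estimate_hurst(UniformTimeSeries(np.full(900, 3.3), 1.0))

    def test_hurst_identity_and_parameter_recovery(self):
        # mean and spread of the estimator over a beta grid
        for beta in [-0.5, 0.0, 0.5, 1.0, 1.5, 2.0]:
            betas = []
            for seed in range(100):
                fit = estimate_hurst(synthesize_power_law(
                    PowerLawSpec(beta_target=beta, n_samples=900, seed=seed)))
                assert fit.hurst_extended == (fit.beta + 1) / 2
                betas.append(fit.beta)
            assert abs(np.mean(betas) - beta) < 0.1
            assert np.std(betas) < 0.25

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=1000))
    def test_affine_invariance(self, scale, seed):
        series = white_noise_series(seed)
        base = estimate_hurst(series)
        scaled = estimate_hurst(UniformTimeSeries(series.values * scale, 1.0))
        assert scaled.beta == pytest.approx(base.beta, abs=1e-9)
        assert scaled.signal_class == base.signal_class
        assert scaled.intercept - base.intercept == pytest.approx(
            2 * np.log10(scale), abs=1e-9)


class TestClassicalConversion:
    @pytest.mark.parametrize("beta,expected_h,expected_class", [
        (0.2, 0.6, "fGn"),
        (1.8, 0.4, "fBm"),
        (-0.5, 0.25, "fGn"),
        (1.0, 0.0, "fBm"),  # boundary closed on the nonstationary side
    ])
    def test_direct_formula(self, beta, expected_h, expected_class):
        result = classical_hurst(beta)
        assert result.hurst == pytest.approx(expected_h)
        assert result.signal_class == expected_class

    def test_same_classical_h_betas_differ_by_two(self):
        for h in [0.1, 0.3, 0.5, 0.7, 0.9]:
            gap = classical_to_beta(h, "fBm") - classical_to_beta(h, "fGn")
            assert gap == pytest.approx(2.0, abs=1e-12)
            # round trip
            assert classical_hurst(classical_to_beta(h, "fGn")).hurst == pytest.approx(h)

    def test_nonfinite_beta_rejected(self):
        with pytest.raises(ValueError):
            classical_hurst(np.nan)


class TestVoxelwiseHurst:
    @staticmethod
    def _volume(data):
        return Volume4D(data, voxel_size=(2, 2, 2), tr=1.0)

    def test_homogeneous_phantom_map(self):
        rng = np.random.default_rng(7)
        from fractalbold.synthetic_data import _power_law_batch
        data = _power_law_batch(4 * 4 * 2, 512, 1.0, rng).reshape(4, 4, 2, 512)
        vmap = voxelwise_hurst(self._volume(data), np.ones((4, 4, 2), bool))
        assert np.nanmean(vmap.data) == pytest.approx(1.0, abs=0.05)

    def test_two_region_ordering_and_mask_sentinels(self):
        from fractalbold.synthetic_data import _power_law_batch
        labels = np.zeros((4, 4, 2), dtype=np.int16)
        labels[:2] = 1
        labels[2:] = 2
        labels[0, 0, 0] = 0  # background voxel -> NaN in the map
        atlas = LabelAtlas(labels, {1: "low", 2: "high"})
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = np.empty((4, 4, 2, 512))
            data[labels == 1] = _power_law_batch(15, 512, 0.6, rng)
            data[labels == 2] = _power_law_batch(16, 512, 1.6, rng)
            data[labels == 0] = rng.standard_normal((1, 512))
            vmap = voxelwise_hurst(self._volume(data), atlas)
            assert np.isnan(vmap.data[0, 0, 0])
            low = np.nanmean(vmap.data[labels == 1])
            high = np.nanmean(vmap.data[labels == 2])
            assert high > low

    def test_constant_voxel_becomes_nan(self):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((2, 2, 2, 512))
        data[0, 0, 0] = 5.0
        vmap = voxelwise_hurst(self._volume(data), np.ones((2, 2, 2), bool))
        assert np.isnan(vmap.data[0, 0, 0])
        assert np.isfinite(vmap.data[1, 1, 1])

    def test_vectorized_path_matches_scalar_path(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((3, 2, 2, 512))
        vmap = voxelwise_hurst(self._volume(data), np.ones((3, 2, 2), bool))
        for idx in [(0, 0, 0), (2, 1, 1)]:
            fit = estimate_hurst(UniformTimeSeries(data[idx], 1.0))
            assert vmap.data[idx] == pytest.approx(fit.hurst_extended, abs=1e-9)

    def test_empty_mask_and_grid_mismatch_rejected(self):
        rng = np.random.default_rng(5)
        vol = self._volume(rng.standard_normal((2, 2, 2, 512)))
        with pytest.raises(ValueError, match="empty"):
            voxelwise_hurst(vol, np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="grid"):
            voxelwise_hurst(vol, np.ones((3, 2, 2), bool))
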