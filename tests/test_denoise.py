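import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluorotax.denoise import (GAUSSIAN_SIGMA_PRESETS, WaveletLevelError,
                               WindowWeights, apply_threshold, dwt,
                               estimate_noise_scale, gaussian_window, idwt,
                               savgol_smooth, square_window,
                               universal_threshold, wavelet_denoise,
                               wma_smooth)
from fluorotax.spectra import Spectrum


def spec_from(values):
    values = np.asarray(values, dtype=float)
    return Spectrum(np.arange(float(len(values))), values)


def brute_force_wma(x, weights):
    """Independent oracle: explicit weighted mean with reflect padding."""
    p = len(weights) // 2
    padded = np.pad(x, p, mode="reflect")
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        acc = 0.0
        for rho in range(-p, p + 1):
            # y(l) = sum w(rho) x(l - rho): w is symmetric in all uses here
            acc += weights[rho + p] * padded[i + p - rho]
        out[i] = acc / sum(weights)
    return out


class TestWMA:
    def test_identity_window(self):
        s = spec_from([3.0, 1.0, 4.0, 1.0, 5.0])
        out = wma_smooth(s, WindowWeights([1.0]))
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_constant_signal_invariant(self):
        s = spec_from(np.full(20, 7.5))
        out = wma_smooth(s, gaussian_window(1.56))
        np.testing.assert_allclose(out.intensities, 7.5, rtol=1e-12)

    def test_hand_example_with_reflection(self):
        s = spec_from([1, 2, 3, 4, 5])
        out = wma_smooth(s, WindowWeights([1, 1, 1]))
        np.testing.assert_allclose(out.intensities,
                                   [5 / 3, 2, 3, 4, 13 / 3])

    @pytest.mark.parametrize("weights", [[1, 1, 1], [1, 2, 1],
                                         [0.2, 1, 2, 1, 0.2]])
    def test_matches_brute_force_oracle(self, rng, weights):
        x = rng.normal(size=50)
        out = wma_smooth(spec_from(x), WindowWeights(weights))
        np.testing.assert_allclose(out.intensities,
                                   brute_force_wma(x, weights), atol=1e-12)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            wma_smooth(spec_from([1, 2, 3]), WindowWeights([1] * 5))


class TestGaussianWindow:
    def test_preset_sigma1_halfwidth(self):
        w = gaussian_window(GAUSSIAN_SIGMA_PRESETS[0])  # sigma = 1.04
        assert w.half_width == 4
        assert w.weights[w.half_width] == 1.0
        np.testing.assert_allclose(w.weights, w.weights[::-1])

    def test_sigma2_first_offset_value(self):
        w = gaussian_window(1.56)
        expected = math.exp(-1.0 / (2 * 1.56 ** 2))
        assert w.weights[w.half_width + 1] == pytest.approx(expected,
                                                            abs=1e-12)
        assert expected == pytest.approx(0.814, abs=5e-4)

    def test_tiny_sigma_with_span_zero_is_identity(self):
        w = gaussian_window(1e-9, span=0)
        np.testing.assert_array_equal(w.weights, [1.0])

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_window(0.0)


def savgol_center_coeffs_bruteforce(window, order):
    """Solve the least-squares normal equations for the centre value."""
    p = window // 2
    a = np.vander(np.arange(-p, p + 1, dtype=float), order + 1,
                  increasing=True)
    # centre value of the fitted polynomial = b_0 = e_0^T (A^T A)^-1 A^T x
    return np.linalg.solve(a.T @ a, a.T)[0]


class TestSavitzkyGolay:
    def test_reproduces_quadratic_exactly(self, band_grid):
        y = 0.01 * (band_grid - 680) ** 2 - 0.3 * (band_grid - 680) + 2
        out = savgol_smooth(Spectrum(band_grid, y), window=13, order=2)
        np.testing.assert_allclose(out.intensities[6:-6], y[6:-6],
                                   atol=1e-9)

    def test_window5_coefficients_match_normal_equations(self, rng):
        coeffs = savgol_center_coeffs_bruteforce(5, 2)
        np.testing.assert_allclose(coeffs,
                                   np.array([-3, 12, 17, 12, -3]) / 35,
                                   atol=1e-12)
        # and the filter output applies exactly those coefficients
        x = rng.normal(size=30)
        out = savgol_smooth(spec_from(x), window=5, order=2)
        interior = np.array([coeffs @ x[i - 2:i + 3] for i in range(2, 28)])
        np.testing.assert_allclose(out.intensities[2:28], interior,
                                   atol=1e-10)

    @pytest.mark.parametrize("window", [13, 17, 23])
    def test_length_preserved(self, band_grid, window):
        y = np.sin(band_grid / 10)
        out = savgol_smooth(Spectrum(band_grid, y), window=window)
        assert out.intensities.size == 101

    def test_even_window_rejected(self, smooth_spectrum):
        with pytest.raises(ValueError):
            savgol_smooth(smooth_spectrum, window=12)

    def test_order_ge_window_rejected(self, smooth_spectrum):
        with pytest.raises(ValueError):
            savgol_smooth(smooth_spectrum, window=5, order=5)


class TestDWT:
    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=64, max_value=256), st.integers(0, 2 ** 31))
    def test_perfect_reconstruction(self, n, seed):
        x = np.random.default_rng(seed).normal(size=n)
        level = min(6, int(math.log2(n)))
        rec = idwt(dwt(x, level=level))
        np.testing.assert_allclose(rec, x, atol=1e-8)

    def test_constant_signal_zero_details(self):
        d = dwt(np.full(128, 3.0), level=5)
        for lvl in range(1, 6):
            assert np.max(np.abs(d.detail(lvl))) < 1e-8

    def test_band_level6_decomposition_exists(self, band_grid):
        import pywt
        x = np.sin(band_grid / 7)
        d = dwt(x, level=6)
        assert d.level == 6 and len(d.details) == 6
        # cross-check coefficient counts against the reference transform
        ref = pywt.wavedec(x, "db9", mode="symmetric", level=6)
        assert d.approx.size == ref[0].size
        assert [d.detail(i).size for i in range(6, 0, -1)] == \
            [c.size for c in ref[1:]]

    def test_too_deep_level_rejected(self):
        with pytest.raises(WaveletLevelError):
            dwt(np.arange(16.0), level=5)


class TestNoiseScaleAndThreshold:
    def test_zero_details_give_zero_scale(self):
        d = dwt(np.full(128, 2.0), level=3)
        d.details[0] = np.zeros_like(d.details[0])
        assert estimate_noise_scale(d) == 0.0

    def test_unit_median_example(self):
        d = dwt(np.zeros(64), level=2)
        d.details[0] = np.array([-1.0, 1.0, -1.0, 1.0])
        assert estimate_noise_scale(d) == pytest.approx(1 / 0.6745,
                                                        abs=1e-12)

    def test_gaussian_noise_scale_consistency(self):
        x = np.random.default_rng(7).normal(size=1024)
        xi = estimate_noise_scale(dwt(x, level=6))
        assert 0.9 <= xi <= 1.1

    @pytest.mark.parametrize("n,xi,expected", [
        (101, 1.0, math.sqrt(2 * math.log(101))),
        (1024, 2.0, 2 * math.sqrt(2 * math.log(1024))),
    ])
    def test_universal_threshold_formula(self, n, xi, expected):
        assert universal_threshold(n, xi) == pytest.approx(expected,
                                                           abs=1e-12)

    def test_universal_threshold_zero_scale(self):
        assert universal_threshold(101, 0.0) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            universal_threshold(1, 1.0)


class TestThresholding:
    def setup_method(self):
        self.decomp = dwt(np.random.default_rng(0).normal(size=128), level=4)

    def test_soft_rule_pointwise(self):
        d = self.decomp.copy()
        d.details[0] = np.array([5.0, -5.0, 1.5, 0.0])
        out = apply_threshold(d, 2.0, "soft")
        np.testing.assert_allclose(out.detail(1), [3.0, -3.0, 0.0, 0.0])

    def test_hard_rule_pointwise(self):
        d = self.decomp.copy()
        d.details[0] = np.array([5.0, -5.0, 1.5, 2.0])
        out = apply_threshold(d, 2.0, "hard")
        np.testing.assert_allclose(out.detail(1), [5.0, -5.0, 0.0, 0.0])

    def test_soft_is_continuous_and_hard_identity_outside(self):
        grid = np.linspace(-4, 4, 401)
        d = self.decomp.copy()
        d.details[0] = grid.copy()
        soft = apply_threshold(d, 1.0, "soft").detail(1)
        np.testing.assert_allclose(soft, np.sign(grid)
                                   * np.maximum(np.abs(grid) - 1.0, 0))
        hard = apply_threshold(d, 1.0, "hard").detail(1)
        outside = np.abs(grid) > 1.0
        np.testing.assert_array_equal(hard[outside], grid[outside])
        assert np.all(hard[~outside] == 0)

    def test_zero_threshold_is_identity(self):
        for mode in ("soft", "hard"):
            out = apply_threshold(self.decomp, 0.0, mode)
            for lvl in range(1, 5):
                np.testing.assert_array_equal(out.detail(lvl),
                                              self.decomp.detail(lvl))

    def test_approximation_untouched(self):
        out = apply_threshold(self.decomp, 10.0, "soft")
        np.testing.assert_array_equal(out.approx, self.decomp.approx)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            apply_threshold(self.decomp, -1.0, "soft")


class TestWaveletDenoise:
    def test_smooth_signal_nearly_preserved(self, smooth_spectrum):
        out = wavelet_denoise(smooth_spectrum, mode="soft")
        # noiseless input: threshold is driven by the (tiny) fine-scale
        # content, so the output stays close to the input
        resid = np.abs(out.intensities - smooth_spectrum.intensities)
        d = dwt(smooth_spectrum.intensities)
        thr = universal_threshold(101, estimate_noise_scale(d))
        assert resid.max() < 3 * thr + 1e-9

    @pytest.mark.parametrize("mode", ["soft", "hard"])
    def test_pure_noise_variance_reduced(self, mode):
        x = np.random.default_rng(11).normal(size=1024)
        s = Spectrum(np.arange(1024.0), x)
        out = wavelet_denoise(s, level=6, mode=mode)
        assert np.var(out.intensities) < 0.15 * np.var(x)

    def test_length_preserved_on_band(self, band_grid):
        x = np.random.default_rng(5).normal(size=101)
        out = wavelet_denoise(Spectrum(band_grid, x))
        assert out.intensities.size == 101
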