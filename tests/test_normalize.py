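import numpy as np
import pytest

from fluorotax.denoise import dwt
from fluorotax.normalize import (DegenerateDenominatorWarning, GSMModel,
                                 RankError, fit_gsm, fit_sbn,
                                 gsm_normalize, minmax_normalize,
                                 sbn_normalize, sbn_unit_normalize,
                                 snv_normalize)
from fluorotax.spectra import SpectraSet, Spectrum
from fluorotax.synth import SynthConfig, generate_cultures


def spec_from(values, grid=None):
    values = np.asarray(values, dtype=float)
    if grid is None:
        grid = np.arange(float(len(values)))
    return Spectrum(grid, values)


class TestMinMax:
    def test_simple_example(self):
        out = minmax_normalize(spec_from([2, 4, 6]), 0, 1)
        np.testing.assert_allclose(out.intensities, [0, 0.5, 1])

    def test_already_normalized_identity(self):
        out = minmax_normalize(spec_from([0.0, 0.25, 1.0]), 0, 1)
        np.testing.assert_allclose(out.intensities, [0.0, 0.25, 1.0])

    def test_asymmetric_range(self):
        out = minmax_normalize(spec_from([-1.0, 0.0, 3.0]), 0, 2)
        np.testing.assert_allclose(out.intensities, [0.0, 0.5, 2.0])

    def test_extremes_exact_and_order_preserved(self, rng):
        x = rng.normal(size=101)
        out = minmax_normalize(spec_from(x), 0.2, 3.4).intensities
        assert out.min() == 0.2 and out.max() == 3.4
        np.testing.assert_array_equal(np.argsort(out), np.argsort(x))

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize(spec_from([1.0, 1.0, 1.0]), 0, 1)


class TestSNV:
    def test_three_point_example(self):
        out = snv_normalize(spec_from([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.intensities,
                                   [-1.2247449, 0.0, 1.2247449], atol=1e-6)

    def test_moments_match_targets(self, rng):
        for _ in range(50):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 10), size=64)
            out = snv_normalize(spec_from(x), mu_tot=0.7,
                                var_tot=2.5).intensities
            assert out.mean() == pytest.approx(0.7, abs=1e-9)
            assert np.var(out) == pytest.approx(2.5, abs=1e-9)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=64)
        a = snv_normalize(spec_from(x)).intensities
        b = snv_normalize(spec_from(3.7 * x + 11.0)).intensities
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            snv_normalize(spec_from([2.0, 2.0, 2.0]))


class TestGSMFit:
    def test_exact_linear_data_recovered(self, band_grid):
        shape = np.exp(-((band_grid - 680.0) ** 2) / 200.0)
        maxima = np.array([1.0, 2.5, 4.0, 7.0, 10.0])
        values = maxima[:, None] * shape
        model = fit_gsm(SpectraSet(band_grid, values))
        np.testing.assert_allclose(model.slope, shape, atol=1e-9)
        np.testing.assert_allclose(model.intercept, 0.0, atol=1e-9)

    def test_unit_slope_at_peak_wavelength(self, band_grid, rng):
        shape = np.exp(-((band_grid - 680.0) ** 2) / 200.0)
        maxima = np.linspace(1, 10, 12)
        values = maxima[:, None] * shape + rng.normal(0, 1e-3,
                                                      size=(12, 101))
        model = fit_gsm(SpectraSet(band_grid, values))
        peak = np.argmax(shape)
        assert model.slope[peak] == pytest.approx(1.0, abs=0.01)
        assert model.intercept[peak] == pytest.approx(0.0, abs=0.05)

    def test_two_point_regression_by_hand(self, band_grid):
        shape = np.exp(-((band_grid - 680.0) ** 2) / 300.0)
        values = np.vstack([1.0 * shape, 2.0 * shape])
        model = fit_gsm(SpectraSet(band_grid, values))
        np.testing.assert_allclose(model.slope, shape / shape.max(),
                                   atol=1e-12)
        np.testing.assert_allclose(model.intercept, 0.0, atol=1e-12)

    def test_equal_maxima_rejected(self, band_grid):
        shape = np.exp(-((band_grid - 680.0) ** 2) / 200.0)
        with pytest.raises(RankError):
            fit_gsm(SpectraSet(band_grid, np.vstack([shape, shape])))


class TestGSMNormalize:
    def make_model(self, grid, slope, intercept, target=1.0):
        return GSMModel(grid, np.asarray(slope, float),
                        np.asarray(intercept, float), target)

    def test_target_equals_measured_is_identity(self, band_grid, rng):
        x = rng.uniform(0.5, 1.0, size=101)
        x[50] = 1.0  # maximum equals the model target
        model = self.make_model(band_grid, rng.uniform(0.1, 1, 101),
                                rng.uniform(0, 0.1, 101), target=1.0)
        out = gsm_normalize(spec_from(x, band_grid), model)
        np.testing.assert_allclose(out.intensities, x, atol=1e-12)

    def test_zero_intercept_is_pure_rescaling(self, band_grid, rng):
        slope = rng.uniform(0.2, 1.0, size=101)
        slope[50] = 1.0
        x = 10.0 * slope  # measured maximum = 10
        model = self.make_model(band_grid, slope, np.zeros(101), target=1.0)
        out = gsm_normalize(spec_from(x, band_grid), model)
        np.testing.assert_allclose(out.intensities, x / 10.0, atol=1e-12)

    def test_scalar_factor_example(self, band_grid):
        slope = np.full(101, 0.5)
        x = np.full(101, 5.0)
        x[0] = 10.0
        model = self.make_model(band_grid, slope, np.zeros(101), target=1.0)
        out = gsm_normalize(spec_from(x, band_grid), model)
        # factor = (0.5*1)/(0.5*10) = 0.1 everywhere
        np.testing.assert_allclose(out.intensities, x * 0.1, atol=1e-12)

    def test_degenerate_denominator_clamped_with_warning(self, band_grid):
        slope = np.zeros(101)
        slope[50] = 1.0
        model = self.make_model(band_grid, slope, np.zeros(101))
        x = np.ones(101)
        with pytest.warns(DegenerateDenominatorWarning):
            out = gsm_normalize(spec_from(x, band_grid), model)
        np.testing.assert_array_equal(out.intensities[:50], x[:50])

    def test_collapses_growth_series(self):
        sigma = 0.01
        data = generate_cultures(SynthConfig(noise_sigma=sigma, seed=9))
        one = data.subset([i for i, l in enumerate(data.labels)
                           if l == "Duna"])
        model = fit_gsm(one)
        normed = np.vstack([
            gsm_normalize(s, model).intensities for s in one.spectra()])
        rms = []
        for i in range(len(normed)):
            for j in range(i + 1, len(normed)):
                rms.append(np.sqrt(np.mean((normed[i] - normed[j]) ** 2)))
        assert max(rms) < 3 * sigma


class TestSBN:
    def test_scalar_multiple_training_regressions_through_origin(
            self, band_grid):
        shape = np.exp(-((band_grid - 680.0) ** 2) / 250.0)
        maxima = np.array([1.0, 3.0, 5.0, 8.0, 10.0])
        model = fit_sbn(SpectraSet(band_grid, maxima[:, None] * shape))
        for key, (slope, intercept) in model.regressions[
                "detail_sigma"].items():
            assert abs(intercept) <= 1e-6 * abs(slope) * 10.0 + 1e-12
        s_slope, s_int = model.regressions["approx_sigma"]
        assert abs(s_int) <= 1e-6 * abs(s_slope) * 10.0 + 1e-12

    def test_no_detail_mean_regressions_fitted(self, band_grid):
        shape = np.exp(-((band_grid - 680.0) ** 2) / 250.0)
        maxima = np.linspace(1, 10, 6)
        model = fit_sbn(SpectraSet(band_grid, maxima[:, None] * shape))
        assert set(model.regressions) == {"approx_mu", "approx_sigma",
                                          "detail_sigma"}

    def test_detail_sigma_slope_ordering(self, band_grid):
        # smooth signals concentrate energy at coarse scales: the sigma-
        # vs-maximum slope shrinks as the detail level gets finer
        shape = np.exp(-((band_grid - 680.0) ** 2) / 250.0)
        maxima = np.linspace(1, 10, 8)
        model = fit_sbn(SpectraSet(band_grid, maxima[:, None] * shape),
                        retained=(3, 6))
        slopes = [model.regressions["detail_sigma"][lvl][0]
                  for lvl in (3, 4, 5, 6)]
        assert slopes[0] < slopes[1] < slopes[2] < slopes[3]

    def test_normalized_levels_hit_variance_targets(self, rng):
        # verified on a dyadic grid with the orthogonal (periodization)
        # boundary, where re-decomposition recovers the construction
        grid = np.arange(600.0, 728.0)
        shape = np.exp(-((grid - 664.0) ** 2) / 250.0)
        maxima = np.linspace(1, 10, 10)
        train = SpectraSet(grid,
                           maxima[:, None] * shape
                           + rng.normal(0, 0.01, size=(10, 128)))
        model = fit_sbn(train, boundary="periodization")
        out = sbn_normalize(train.spectrum(4), model)
        decomp = dwt(out.intensities, wavelet=model.wavelet,
                     level=model.level, boundary="periodization")
        for lvl in range(3, 7):
            sd = np.std(decomp.detail(lvl))
            assert sd == pytest.approx(abs(model.sigma_details[lvl]),
                                       rel=1e-6)

    def test_scalar_multiples_map_to_identical_outputs(self, band_grid):
        shape = np.exp(-((band_grid - 680.0) ** 2) / 250.0)
        maxima = np.linspace(1, 10, 6)
        train = SpectraSet(band_grid, maxima[:, None] * shape)
        model = fit_sbn(train)
        a = sbn_normalize(spec_from(2.0 * shape, band_grid), model)
        b = sbn_normalize(spec_from(7.0 * shape, band_grid), model)
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-6)

    def test_own_statistics_reproduce_input_minus_fine_levels(
            self, band_grid):
        shape = (np.exp(-((band_grid - 680.0) ** 2) / 250.0)
                 + 0.2 * np.sin(band_grid / 3.0))
        spec = spec_from(5.0 * shape, band_grid)
        decomp = dwt(spec.intensities)
        from fluorotax.normalize import SBNModel
        model = SBNModel(
            wavelet="db9", level=6, retained=(3, 6), target_max=5.0,
            mu_approx=float(decomp.approx.mean()),
            sigma_approx=float(np.std(decomp.approx)),
            sigma_details={lvl: float(np.std(decomp.detail(lvl)))
                           for lvl in range(3, 7)})
        out = sbn_normalize(spec, model)
        # reference: same decomposition with D_1, D_2 removed
        ref = decomp.copy()
        ref.details[0] = np.zeros_like(ref.details[0])
        ref.details[1] = np.zeros_like(ref.details[1])
        from fluorotax.denoise import idwt
        np.testing.assert_allclose(out.intensities, idwt(ref), atol=1e-8)

    def test_reduces_to_snv_in_the_dyadic_full_level_limit(self, rng):
        y = rng.normal(size=128).cumsum()
        spec = spec_from(y)
        a = sbn_unit_normalize(spec, level=7, retained=(1, 7),
                               boundary="periodization").intensities
        b = snv_normalize(spec).intensities
        np.testing.assert_allclose(a, b, atol=1e-6)
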