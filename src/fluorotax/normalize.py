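"""Normalization of fluorescence spectra across growth states.

Fluorescence amplitude varies strongly with culture growth state while
the spectral shape is (to first order) preserved, so spectra must be put
on a common scale before distance-based classification. Four methods:

* **Min-Max** — affine map of each spectrum into a fixed range [a, b].
* **GSM** (growing spectra modeling) — per-wavelength linear regressions
  of fluorescence against the spectrum maximum, ``Fl_l(m) = a_l m + b_l``,
  fitted across growth states; each value is rescaled by
  ``Fl_l(target_max) / Fl_l(m_measured)``.
* **SNV** (standard normal variate) — per-spectrum standardisation to a
  target mean and variance (defaults 0 and 1).
* **Modified SBN** (scale-based normalization) — SNV applied level by
  level in the wavelet domain, with each retained level rescaled to
  regression-predicted mean/variance targets so the inter-level energy
  relationships that carry taxonomic information are preserved.

Population (divide-by-n) variance is used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .denoise import (DEFAULT_LEVEL, DEFAULT_WAVELET,
                      WaveletDecomposition, dwt, idwt)
from .spectra import SpectraSet, Spectrum

__all__ = [
    "GSMModel",
    "SBNModel",
    "RankError",
    "DegenerateDenominatorWarning",
    "minmax_normalize",
    "fit_gsm",
    "gsm_normalize",
    "snv_normalize",
    "fit_sbn",
    "sbn_normalize",
    "sbn_unit_normalize",
]


class RankError(ValueError):
    """Training spectra maxima are all equal; regression is rank-deficient."""


class DegenerateDenominatorWarning(RuntimeWarning):
    """A normalization factor was clamped on a degenerate denominator."""


def minmax_normalize(spec: Spectrum, a: float = 0.0,
                     b: float = 1.0) -> Spectrum:
    """Affine map of the spectrum into [a, b]; extremes land exactly on a, b."""
    if a >= b:
        raise ValueError("need a < b")
    x = spec.intensities
    lo, hi = x.min(), x.max()
    if hi <= lo:
        raise ValueError("constant spectrum: min == max, range is degenerate")
    return spec.replace_intensities(a + (x - lo) * (b - a) / (hi - lo))


def _ols_1d(m: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-column OLS of y (n x p) on m (n,): slope, intercept."""
    m = np.asarray(m, dtype=float)
    mbar = m.mean()
    dm = m - mbar
    denom = np.dot(dm, dm)
    if denom <= 0:
        raise RankError("regressor (spectrum maxima) has zero variance")
    slope = dm @ (y - y.mean(axis=0)) / denom
    intercept = y.mean(axis=0) - slope * mbar
    return slope, intercept


@dataclass
class GSMModel:
    """Per-wavelength linear model Fl_l(m) = a_l m + b_l of fluorescence
    against the spectrum maximum m, plus the target maximum to normalise to."""

    grid: np.ndarray
    slope: np.ndarray       # a_l
    intercept: np.ndarray   # b_l
    target_max: float = 1.0

    def predict(self, m: float) -> np.ndarray:
        """Fl_l evaluated at spectrum maximum m."""
        return self.slope * m + self.intercept

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.tolist(),
            "slope": self.slope.tolist(),
            "intercept": self.intercept.tolist(),
            "target_max": self.target_max,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GSMModel":
        return cls(np.asarray(d["grid"], float), np.asarray(d["slope"], float),
                   np.asarray(d["intercept"], float), float(d["target_max"]))


def fit_gsm(train: SpectraSet, target_max: float = 1.0) -> GSMModel:
    """Fit the growing-spectra model on a training set.

    Requires >= 2 spectra whose band maxima are not all equal. At the
    wavelength of the emission maximum the fitted slope is ~1 and the
    intercept ~0, since fluorescence there *is* the maximum.
    """
    if train.n_measurements < 2:
        raise ValueError("need >= 2 training spectra")
    m = train.values.max(axis=1)
    slope, intercept = _ols_1d(m, train.values)
    return GSMModel(train.grid.copy(), slope, intercept, float(target_max))


def gsm_normalize(spec: Spectrum, model: GSMModel,
                  eps: float = 1e-12) -> Spectrum:
    """Rescale each wavelength by Fl_l(target_max) / Fl_l(m_measured).

    Wavelengths where the fitted denominator is degenerate
    (|Fl_l(m)| < eps) keep their value (factor clamped to 1); a warning
    reports how many were clamped.
    """
    if model.grid.shape != spec.wavelengths.shape or not np.allclose(
            model.grid, spec.wavelengths):
        raise ValueError("model grid does not match the spectrum grid")
    m = float(spec.intensities.max())
    denom = model.predict(m)
    numer = model.predict(model.target_max)
    degenerate = np.abs(denom) < eps
    factor = np.where(degenerate, 1.0, numer / np.where(degenerate, 1.0, denom))
    n_bad = int(degenerate.sum())
    if n_bad:
        warnings.warn(
            f"gsm_normalize: clamped {n_bad} degenerate factor(s) to 1",
            DegenerateDenominatorWarning, stacklevel=2)
    return spec.replace_intensities(spec.intensities * factor)


def snv_normalize(spec: Spectrum, mu_tot: float = 0.0,
                  var_tot: float = 1.0) -> Spectrum:
    """Standard normal variate: match the spectrum's mean/variance to targets.

    y(l) = (x(l) - mu + mu_tot) * sqrt(var_tot / var), with mu and var the
    spectrum's own mean and population variance. With the default targets
    the output has mean 0 and variance 1 exactly; the map is invariant to
    affine transformations of the input.
    """
    x = spec.intensities
    var = float(np.var(x))
    if var <= 0:
        raise ValueError("zero-variance spectrum cannot be standardised")
    y = (x - x.mean() + mu_tot) * np.sqrt(var_tot / var)
    # match the mean target exactly even when mu_tot != 0 scales through
    y = y - y.mean() + mu_tot
    return spec.replace_intensities(y)


# ---------------------------------------------------------------------------
# Scale-based normalization
# ---------------------------------------------------------------------------

def _level_stats(decomp: WaveletDecomposition,
                 retained: tuple[int, int]) -> dict:
    """Population mean/std of the approximation and retained detail levels."""
    i, j = retained
    stats = {"approx_mu": float(decomp.approx.mean()),
             "approx_sigma": float(np.std(decomp.approx)),
             "detail_sigma": {lvl: float(np.std(decomp.detail(lvl)))
                              for lvl in range(i, j + 1)}}
    return stats


@dataclass
class SBNModel:
    """Regression targets for the modified scale-based normalization.

    Per-level linear regressions of coefficient statistics against the
    spectrum maximum, evaluated at ``target_max``: the approximation gets
    mean and standard-deviation targets, each retained detail level a
    standard-deviation target only (detail means are zero by construction,
    so no mean regression is fitted for them).
    """

    wavelet: str
    level: int
    retained: tuple[int, int]      # (i, j), coarsest retained detail range
    target_max: float
    mu_approx: float               # regression of A_L mean, at target_max
    sigma_approx: float            # regression of A_L std, at target_max
    sigma_details: dict[int, float]  # level -> std target
    boundary: str = "symmetric"
    # raw regression coefficients, kept for inspection/serialisation
    regressions: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        return {
            "wavelet": self.wavelet, "level": self.level,
            "retained": list(self.retained), "target_max": self.target_max,
            "mu_approx": self.mu_approx, "sigma_approx": self.sigma_approx,
            "sigma_details": {str(k): v for k, v in self.sigma_details.items()},
            "boundary": self.boundary,
            "regressions": self.regressions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SBNModel":
        return cls(d["wavelet"], int(d["level"]), tuple(d["retained"]),
                   float(d["target_max"]), float(d["mu_approx"]),
                   float(d["sigma_approx"]),
                   {int(k): float(v) for k, v in d["sigma_details"].items()},
                   d.get("boundary", "symmetric"), d.get("regressions", {}))


def fit_sbn(train: SpectraSet, wavelet: str = DEFAULT_WAVELET,
            level: int = DEFAULT_LEVEL, retained: tuple[int, int] = (3, 6),
            target_max: float = 1.0,
            boundary: str = "symmetric") -> SBNModel:
    """Fit the modified-SBN regression targets on a training set.

    For every training spectrum the wavelet statistics (A_L mean and std,
    retained D_i..D_j stds) are regressed against the spectrum maximum;
    the regressions are evaluated at ``target_max`` to give the
    normalisation targets.
    """
    i, j = retained
    if not (1 <= i <= j <= level):
        raise ValueError(f"retained range {retained} must satisfy "
                         f"1 <= i <= j <= level ({level})")
    if train.n_measurements < 2:
        raise ValueError("need >= 2 training spectra")
    m = train.values.max(axis=1)

    rows = []
    for k in range(train.n_measurements):
        decomp = dwt(train.values[k], wavelet=wavelet, level=level,
                     boundary=boundary)
        s = _level_stats(decomp, retained)
        rows.append([s["approx_mu"], s["approx_sigma"]]
                    + [s["detail_sigma"][lvl] for lvl in range(i, j + 1)])
    stats = np.asarray(rows)
    slope, intercept = _ols_1d(m, stats)

    at_target = slope * target_max + intercept
    regressions = {
        "approx_mu": (float(slope[0]), float(intercept[0])),
        "approx_sigma": (float(slope[1]), float(intercept[1])),
        "detail_sigma": {lvl: (float(slope[2 + n]), float(intercept[2 + n]))
                         for n, lvl in enumerate(range(i, j + 1))},
    }
    return SBNModel(
        wavelet, level, (i, j), float(target_max),
        mu_approx=float(at_target[0]), sigma_approx=float(at_target[1]),
        sigma_details={lvl: float(at_target[2 + n])
                       for n, lvl in enumerate(range(i, j + 1))},
        boundary=boundary, regressions=regressions,
    )


def _standardize_level(coeffs: np.ndarray, sigma_target: float,
                       mu_target: float | None, tiny: float = 1e-12
                       ) -> tuple[np.ndarray, bool]:
    """Rescale one coefficient level to its targets.

    ``mu_target`` None means a detail level: its mean is treated as zero
    (it is, up to boundary effects), so only the variance is rescaled —
    this keeps the rescale an exact identity when the targets equal the
    level's own statistics.
    """
    sd = float(np.std(coeffs))
    if sd < tiny:
        return coeffs, True
    if mu_target is None:
        return coeffs * (sigma_target / sd), False
    return (coeffs - coeffs.mean()) / sd * sigma_target + mu_target, False


def sbn_normalize(spec: Spectrum, model: SBNModel) -> Spectrum:
    """Modified scale-based normalization.

    Decompose; zero detail levels finer than the retained range (noise
    carriers); standardise each retained level to mean 0 / variance 1 and
    rescale to the model's regression targets (details get a variance
    target only, the approximation gets mean and variance); reconstruct.
    A retained level with zero coefficient variance passes through
    unscaled with a warning.
    """
    i, j = model.retained
    decomp = dwt(spec.intensities, wavelet=model.wavelet, level=model.level,
                 boundary=model.boundary)
    out = decomp.copy()
    n_degenerate = 0

    for lvl in range(1, i):
        out.details[lvl - 1] = np.zeros_like(out.details[lvl - 1])
    for lvl in range(i, j + 1):
        scaled, bad = _standardize_level(out.detail(lvl),
                                         model.sigma_details[lvl], None)
        out.details[lvl - 1] = scaled
        n_degenerate += bad
    approx, bad = _standardize_level(out.approx, model.sigma_approx,
                                     model.mu_approx)
    out.approx = approx
    n_degenerate += bad
    if n_degenerate:
        warnings.warn(
            f"sbn_normalize: {n_degenerate} level(s) had zero coefficient "
            "variance and passed through unscaled",
            DegenerateDenominatorWarning, stacklevel=2)
    return spec.replace_intensities(idwt(out))


def sbn_unit_normalize(spec: Spectrum, wavelet: str = DEFAULT_WAVELET,
                       level: int = DEFAULT_LEVEL,
                       retained: tuple[int, int] = (3, 6),
                       boundary: str = "symmetric") -> Spectrum:
    """Unmodified scale-based normalization (unit targets).

    y(l) = (D_i(l) + ... + D_j(l)) / sqrt(sigma_i^2 + ... + sigma_j^2)
    where D_k(l) is the signal-domain reconstruction of detail level k
    and sigma_k^2 its population variance. With an orthonormal transform
    on dyadic lengths and retained = (1, log2 n) this reduces exactly to
    SNV with targets (0, 1), since the detail levels sum to the
    mean-removed signal and their variances add.
    """
    i, j = retained
    decomp = dwt(spec.intensities, wavelet=wavelet, level=level,
                 boundary=boundary)
    total = np.zeros(spec.intensities.size)
    var_sum = 0.0
    for lvl in range(i, j + 1):
        only = decomp.copy()
        only.approx = np.zeros_like(only.approx)
        for other in range(1, level + 1):
            if other != lvl:
                only.details[other - 1] = np.zeros_like(only.detail(other))
        d_sig = idwt(only)
        total += d_sig
        var_sum += float(np.var(d_sig))
    if var_sum <= 0:
        raise ValueError("retained detail levels carry no variance")
    return spec.replace_intensities(total / np.sqrt(var_sum))
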