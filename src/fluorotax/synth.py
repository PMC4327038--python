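"""Synthetic culture spectra and low-cost-sensor degradation.

The generator emulates chlorophyll-a fluorescence emission of five
phytoplankton cultures on the 630-730 nm band at 1-nm resolution. Each
class has a fixed unit-maximum spectral shape built from Gaussian peaks:
the Chl-a emission maximum near 680 nm, a 700-712 nm shoulder, and an
accessory-pigment band at 630-660 nm. A culture's measurement at growth
state g is

    x(l) = m_g * s_c(l) + baseline + eps(l),   eps ~ N(0, sigma^2) i.i.d.

with the spectrum maximum m_g following a logistic growth curve over
[1, 10]. By construction the per-wavelength fluorescence is linear in
the spectrum maximum (slope s_c(l), intercept = baseline), the structure
the growing-spectra normalization model assumes.

Two of the default classes (the Iso/Amin analogues) have near-identical
shapes — the confusable pair — so that classification errors concentrate
between them, as observed with the real cultures.

Sensor degradation mimics a cheaper instrument: spectral resolution
halved (keep every second wavelength) and white Gaussian noise added
(default variance 0.03 in the generator's amplitude units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import SpectraSet

__all__ = [
    "ClassRecipe",
    "SynthConfig",
    "DEFAULT_RECIPES",
    "generate_cultures",
    "downsample",
    "add_gaussian_noise",
    "degrade",
]


@dataclass(frozen=True)
class ClassRecipe:
    """Gaussian-peak recipe for one culture's unit-max spectral shape."""

    name: str
    peak_center: float = 680.0      # Chl-a emission maximum, nm
    peak_width: float = 10.0        # Gaussian sigma, nm
    shoulder_center: float = 710.0  # vibrational shoulder, nm
    shoulder_width: float = 12.0
    shoulder_amp: float = 0.25      # relative to the main peak
    accessory_center: float = 645.0  # accessory-pigment band, nm
    accessory_width: float = 14.0
    accessory_amp: float = 0.18

    def validate(self) -> None:
        for attr in ("peak_width", "shoulder_width", "accessory_width"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{self.name}: {attr} must be positive")
        for attr in ("shoulder_amp", "accessory_amp"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be nonnegative")

    def shape(self, grid: np.ndarray) -> np.ndarray:
        """Unit-maximum spectral shape on the given grid."""
        self.validate()

        def g(center: float, width: float) -> np.ndarray:
            return np.exp(-((grid - center) ** 2) / (2.0 * width ** 2))

        s = (g(self.peak_center, self.peak_width)
             + self.shoulder_amp * g(self.shoulder_center, self.shoulder_width)
             + self.accessory_amp * g(self.accessory_center,
                                      self.accessory_width))
        return s / s.max()


# Five cultures mirroring the measured taxa: a diatom, a green alga, two
# haptophytes and a dinoflagellate. The last two (Amin/Iso analogues) are
# the confusable pair: their shape separation is about half the smallest
# separation among the other classes, calibrated so the optimal chain
# still resolves them on degraded data while weaker chains confuse them.
DEFAULT_RECIPES: tuple[ClassRecipe, ...] = (
    ClassRecipe("Thwi", peak_center=681.0, peak_width=10.0,
                shoulder_center=710.0, shoulder_amp=0.25,
                accessory_center=645.0, accessory_amp=0.18),
    ClassRecipe("Duna", peak_center=678.0, peak_width=9.0,
                shoulder_center=704.0, shoulder_amp=0.32,
                accessory_center=651.0, accessory_amp=0.24),
    ClassRecipe("Pl", peak_center=680.0, peak_width=11.5,
                shoulder_center=713.0, shoulder_amp=0.20,
                accessory_center=648.0, accessory_amp=0.28),
    ClassRecipe("Amin", peak_center=683.0, peak_width=10.0,
                shoulder_center=707.0, shoulder_amp=0.30,
                accessory_center=639.0, accessory_amp=0.13),
    ClassRecipe("Iso", peak_center=684.2, peak_width=11.0,
                shoulder_center=708.0, shoulder_amp=0.25,
                accessory_center=642.0, accessory_amp=0.17),
)

# A clearly distinct fifth class, used when the confusable pair is off.
_DISTINCT_ISO = ClassRecipe("Iso", peak_center=688.0, peak_width=12.5,
                            shoulder_center=716.0, shoulder_amp=0.38,
                            accessory_center=656.0, accessory_amp=0.32)


#: (first sampling, second sampling) measurement counts per default class
DEFAULT_SAMPLING_COUNTS: tuple[tuple[int, int], ...] = (
    (16, 22), (18, 22), (16, 22), (10, 16), (8, 22))


@dataclass
class SynthConfig:
    """Study conditions for the synthetic culture generator.

    The measurement campaign is emulated as two samplings of each
    culture's growth series: the second covers every growth state
    1..S, the first only the later states (the early, too-dilute
    measurements having been discarded), with independent noise in each
    sampling. Per-class (first, second) counts default to the real
    campaign's (16,22), (18,22), (16,22), (10,16), (8,22). The spectrum
    maximum follows a logistic growth curve over ``amplitude_range`` and
    the measurement noise sigma is in the same (arbitrary) units.
    """

    recipes: tuple[ClassRecipe, ...] = DEFAULT_RECIPES
    sampling_counts: tuple[tuple[int, int], ...] = DEFAULT_SAMPLING_COUNTS
    grid_lo: float = 630.0
    grid_hi: float = 730.0
    grid_step: float = 1.0
    amplitude_range: tuple[float, float] = (1.0, 10.0)
    growth_rate: float = 0.35          # logistic steepness per growth step
    noise_sigma: float = 0.05          # additive measurement noise sigma
    baseline: float = 0.0              # per-wavelength intercept b_l
    confusable_pair: bool = True
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if len(self.sampling_counts) != len(self.recipes):
            raise ValueError("sampling_counts must match the recipe count")
        for n1, n2 in self.sampling_counts:
            if not (0 < n1 <= n2):
                raise ValueError("need 0 < first-sampling <= second-sampling "
                                 "count per class")

    @classmethod
    def with_per_class(cls, n_per_class: int, **kwargs) -> "SynthConfig":
        """Equal total measurements per class, split over two samplings."""
        n1, n2 = n_per_class // 2, n_per_class - n_per_class // 2
        recipes = kwargs.get("recipes", DEFAULT_RECIPES)
        return cls(sampling_counts=((n1, n2),) * len(recipes), **kwargs)

    def effective_recipes(self) -> tuple[ClassRecipe, ...]:
        if self.confusable_pair or self.recipes is not DEFAULT_RECIPES:
            return self.recipes
        return self.recipes[:-1] + (_DISTINCT_ISO,)


def _logistic_maxima(n: int, lo: float, hi: float, rate: float) -> np.ndarray:
    """Spectrum maxima across n growth states: logistic from lo to hi."""
    g = np.arange(1, n + 1, dtype=float)
    mid = (n + 1) / 2.0
    curve = 1.0 / (1.0 + np.exp(-rate * (g - mid)))
    # rescale so the first state sits at lo and the last at hi exactly
    curve = (curve - curve[0]) / (curve[-1] - curve[0])
    return lo + curve * (hi - lo)


def generate_cultures(config: SynthConfig | None = None) -> SpectraSet:
    """Generate a labelled multi-growth-state culture spectra set.

    At sigma = 0 every class's spectra are exact scalar multiples of its
    base shape, so the growing-spectra regression recovers slope s_c(l)
    and intercept = baseline exactly. Generation is reproducible
    bit-for-bit given the config seed.
    """
    config = config or SynthConfig()
    rng = np.random.default_rng(config.seed)
    grid = np.arange(config.grid_lo, config.grid_hi + config.grid_step / 2,
                     config.grid_step)
    lo, hi = config.amplitude_range

    rows, labels, growth = [], [], []
    for recipe, (n1, n2) in zip(config.effective_recipes(),
                                config.sampling_counts):
        s = recipe.shape(grid)
        maxima = _logistic_maxima(n2, lo, hi, config.growth_rate)
        # second sampling covers states 1..n2, the first only the later
        # n1 states (early too-dilute measurements discarded)
        states = list(range(n2 - n1 + 1, n2 + 1)) + list(range(1, n2 + 1))
        for g in states:
            x = maxima[g - 1] * s + config.baseline
            if config.noise_sigma > 0:
                x = x + rng.normal(0.0, config.noise_sigma, size=grid.size)
            rows.append(x)
            labels.append(recipe.name)
            growth.append(g)
    return SpectraSet(grid, np.vstack(rows), labels=labels,
                      growth_indices=growth)


def downsample(sset: SpectraSet, factor: int = 2) -> SpectraSet:
    """Reduce spectral resolution: keep every ``factor``-th wavelength
    starting from the first; kept values are unchanged."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return sset.with_values(sset.values.copy())
    return sset.with_values(sset.values[:, ::factor],
                            grid=sset.grid[::factor])


def add_gaussian_noise(sset: SpectraSet, variance: float = 0.03,
                       seed: int | None = None) -> SpectraSet:
    """Add i.i.d. zero-mean Gaussian noise of the given variance."""
    if variance < 0:
        raise ValueError("variance must be nonnegative")
    if variance == 0:
        return sset.with_values(sset.values.copy())
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, np.sqrt(variance), size=sset.values.shape)
    return sset.with_values(sset.values + noise)


def degrade(sset: SpectraSet, factor: int = 2, variance: float = 0.03,
            seed: int | None = None) -> SpectraSet:
    """Low-cost-sensor emulation: downsample, then add Gaussian noise."""
    return add_gaussian_noise(downsample(sset, factor), variance, seed)
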