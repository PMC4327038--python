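import numpy as np
import pytest

from fluorotax.spectra import Spectrum, SpectraSet
from fluorotax.synth import SynthConfig, generate_cultures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def band_grid():
    """The 630-730 nm analysis band at 1-nm resolution (101 points)."""
    return np.arange(630.0, 731.0)


@pytest.fixture
def smooth_spectrum(band_grid):
    """A noiseless broad emission-like peak on the analysis band."""
    y = 5.0 * np.exp(-((band_grid - 680.0) ** 2) / (2 * 12.0 ** 2)) + 0.5
    return Spectrum(band_grid, y)


@pytest.fixture
def noisy_set(band_grid, rng):
    """Ten noisy copies of a fixed peak: fodder for smoothing audits."""
    base = 5.0 * np.exp(-((band_grid - 680.0) ** 2) / (2 * 12.0 ** 2))
    values = base + rng.normal(0, 0.15, size=(10, band_grid.size))
    return SpectraSet(band_grid, values)


@pytest.fixture
def clean_cultures():
    """Noise-free synthetic campaign: exact scalar-multiple growth series."""
    return generate_cultures(SynthConfig(noise_sigma=0.0, seed=3))


@pytest.fixture
def default_cultures():
    """The default synthetic campaign (dual sampling, sigma = 0.05)."""
    return generate_cultures(SynthConfig(seed=3))


@pytest.fixture
def separable_clouds(rng):
    """Five well-separated Gaussian clouds in 8-D, 30 points each."""
    centers = rng.normal(0, 5, size=(5, 8))
    x = np.vstack([c + rng.normal(0, 0.3, size=(30, 8)) for c in centers])
    labels = [f"c{i}" for i in range(5) for _ in range(30)]
    return x, labels
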