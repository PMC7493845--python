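import numpy as np
import pytest

from aneufilt.volume_io import Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    return Volume(rng.random((12, 14, 16)))


def gaussian_blob(shape, center, sigma, amplitude=1.0):
    """Analytic isotropic Gaussian blob volume (shared phantom helper)."""
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return amplitude * np.exp(-d2 / (2.0 * sigma ** 2))


def straight_tube(shape, radius, axis=0, amplitude=1.0):
    """Analytic straight tube along one axis with a Gaussian cross profile."""
    centers = [(n - 1) / 2.0 for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum((g - c) ** 2 for i, (g, c) in enumerate(zip(grids, centers))
             if i != axis)
    return amplitude * np.exp(-d2 / (2.0 * (radius / np.sqrt(2 * np.log(2))) ** 2)) \
        * np.ones(shape)
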