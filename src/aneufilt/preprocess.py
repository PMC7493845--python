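"""Denoising and intensity normalization applied before filtering.

The pipeline runs a 3x3x3 median filter to suppress speckle noise, then
rescales intensities to [0, 1].  Both steps operate on :class:`Volume`
objects and preserve geometry.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .volume_io import Volume

logger = logging.getLogger(__name__)

__all__ = ["median_denoise", "normalize01", "preprocess"]


def median_denoise(volume: Volume, window: int = 3) -> Volume:
    """Median-filter the volume with a cubic ``window**3`` neighborhood.

    Borders are handled by reflection.  ``window`` must be odd and >= 1.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    out = ndimage.median_filter(volume.data, size=window, mode="reflect")
    return volume.with_data(out)


def normalize01(volume: Volume) -> Volume:
    """Rescale intensities to [0, 1] via ``(v - min) / (max - min)``.

    A constant volume maps to all zeros with a logged warning, so the
    detection loop terminates gracefully once removal has emptied the image.
    """
    data = np.asarray(volume.data, dtype=np.float64)
    lo = float(data.min())
    hi = float(data.max())
    if hi == lo:
        logger.warning("normalize01: constant volume (value %g) mapped to zeros", lo)
        return volume.with_data(np.zeros_like(data))
    return volume.with_data((data - lo) / (hi - lo))


def preprocess(volume: Volume, window: int = 3) -> Volume:
    """Median denoise then normalize to [0, 1]."""
    return normalize01(median_denoise(volume, window=window))
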