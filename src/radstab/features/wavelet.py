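"""One-level 3-D stationary (undecimated) wavelet transform, coif1 basis.

Each axis is filtered with the coif1 analysis low/high-pass filter by
circular (periodic) correlation, so every sub-band has the same shape as
the input and stays aligned with the ROI mask.  Sub-bands are named by
one letter per axis in array order ``(z, y, x)``: ``L`` = low-pass,
``H`` = high-pass, e.g. ``LLH`` is low-pass along z and y, high-pass
along x.
"""

from __future__ import annotations

from itertools import product

import numpy as np
from scipy import ndimage

__all__ = ["COIF1_DEC_LO", "COIF1_DEC_HI", "swt3", "SUBBAND_NAMES"]

# coif1 analysis (decomposition) filters.
COIF1_DEC_LO = np.array(
    [
        -0.015655728135791993,
        -0.07273261951252645,
        0.3848648468648578,
        0.8525720202116004,
        0.3378976624574818,
        -0.07273261951252645,
    ]
)
COIF1_DEC_HI = np.array(
    [
        0.07273261951252645,
        0.3378976624574818,
        -0.8525720202116004,
        0.3848648468648578,
        0.07273261951252645,
        -0.015655728135791993,
    ]
)

SUBBAND_NAMES = tuple("".join(c) for c in product("LH", repeat=3))  # LLL..HHH


def _filter_axis(data: np.ndarray, weights: np.ndarray, axis: int) -> np.ndarray:
    # Circular convolution with the centred 6-tap filter; this equals the
    # usual level-1 undecimated analysis convention for even axis lengths.
    return ndimage.convolve1d(data, weights, axis=axis, mode="wrap")


def swt3(volume: np.ndarray) -> dict[str, np.ndarray]:
    """Decompose ``volume`` into the 8 level-1 sub-bands LLL..HHH.

    The low-pass filter has gain ``sum(COIF1_DEC_LO)`` = sqrt(2) per
    axis, so a constant volume maps to ``2**1.5`` times itself in LLL
    and to (numerically) zero in every detail band.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("swt3 expects a 3-D array")
    out: dict[str, np.ndarray] = {}
    for name in SUBBAND_NAMES:
        band = volume
        for axis, letter in enumerate(name):
            weights = COIF1_DEC_LO if letter == "L" else COIF1_DEC_HI
            band = _filter_axis(band, weights, axis)
        out[name] = band
    return out
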