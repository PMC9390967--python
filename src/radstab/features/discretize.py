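"""Grey-level discretisation of in-mask intensities."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiscretizationConfig", "discretize"]


@dataclass
class DiscretizationConfig:
    mode: str = "fixed_bin_width"  # or "fixed_bin_count"
    bin_width: float = 25.0
    bin_count: int = 32

    def __post_init__(self) -> None:
        if self.mode not in ("fixed_bin_width", "fixed_bin_count"):
            raise ValueError(f"unknown discretisation mode {self.mode!r}")
        if self.mode == "fixed_bin_width" and self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.mode == "fixed_bin_count" and self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")


def discretize(
    volume: np.ndarray, mask: np.ndarray, config: DiscretizationConfig
) -> tuple[np.ndarray, int]:
    """Map in-mask voxels to integer levels 1..Ng; voxels outside get 0.

    Fixed bin width: ``level = floor((v - min) / width) + 1`` from the
    in-mask minimum.  Fixed bin count: the in-mask range is split into
    ``bin_count`` equal bins (the maximum falls in the top bin).  A
    constant ROI yields a single level.
    """
    mask = mask.astype(bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = volume[mask]
    vmin = vals.min()
    levels = np.zeros(volume.shape, dtype=np.int64)
    if config.mode == "fixed_bin_width":
        lv = np.floor((vals - vmin) / config.bin_width).astype(np.int64) + 1
    else:
        vmax = vals.max()
        if vmax == vmin:
            lv = np.ones(vals.shape, dtype=np.int64)
        else:
            width = (vmax - vmin) / config.bin_count
            lv = np.minimum(
                np.floor((vals - vmin) / width).astype(np.int64), config.bin_count - 1
            ) + 1
    levels[mask] = lv
    return levels, int(lv.max())
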