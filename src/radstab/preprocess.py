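"""Image normalisation and analysis-slab selection.

The fixed stage order is window -> histogram equalisation -> Gaussian
denoise -> slab selection; identical configuration and input give
identical output.  Spacing metadata passes through untouched except by
the resampling operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import ImageVolume, LesionSample, ROIMask

__all__ = [
    "PreprocessConfig",
    "window_level",
    "equalize_histogram",
    "gaussian_denoise",
    "select_max_area_slices",
    "resample_isotropic",
    "preprocess_sample",
]

# Fallback fixed lung window when an adaptive window degenerates.
LUNG_WINDOW_CENTER_HU = -600.0
LUNG_WINDOW_WIDTH_HU = 1500.0


@dataclass
class PreprocessConfig:
    window_mode: str = "adaptive"  # "fixed" | "adaptive"
    window_center_hu: float = LUNG_WINDOW_CENTER_HU
    window_width_hu: float = LUNG_WINDOW_WIDTH_HU
    equalize: bool = True
    equalize_bins: int = 256
    gauss_sigma_mm: float = 0.75
    n_slices: int = 3
    # Final rescale of the normalised [0, 1] slab to [0, rescale_max] so
    # that fixed-bin-width discretisation downstream has dynamic range to
    # work with; 0 disables.
    rescale_max: float = 255.0

    def __post_init__(self) -> None:
        if self.window_width_hu <= 0:
            raise ValueError("window_width_hu must be > 0")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.equalize_bins < 2:
            raise ValueError("equalize_bins must be >= 2")
        if self.window_mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown window_mode {self.window_mode!r}")


def window_level(
    volume: ImageVolume,
    config: PreprocessConfig,
    mask: ROIMask | None = None,
) -> ImageVolume:
    """Clip to the window and rescale affinely to [0, 1].

    Adaptive mode sets center to the in-ROI mean and width to 6x the
    in-ROI SD (mean +/- 3 SD); a zero-variance ROI falls back to the
    fixed lung window with a warning.
    """
    center, width = config.window_center_hu, config.window_width_hu
    if config.window_mode == "adaptive":
        if mask is None:
            raise ValueError("adaptive windowing requires a mask")
        roi = volume.data[mask.data]
        sd = float(roi.std())
        if sd == 0.0:
            warnings.warn(
                "zero-variance ROI: adaptive window undefined, "
                "falling back to the fixed lung window",
                stacklevel=2,
            )
            center, width = LUNG_WINDOW_CENTER_HU, LUNG_WINDOW_WIDTH_HU
        else:
            center, width = float(roi.mean()), 6.0 * sd
    lo, hi = center - width / 2.0, center + width / 2.0
    out = (np.clip(volume.data, lo, hi) - lo) / (hi - lo)
    return ImageVolume(out, volume.spacing)


def equalize_histogram(volume: ImageVolume, bins: int = 256) -> ImageVolume:
    """Classic CDF-mapping histogram equalisation.

    Each voxel maps to the empirical CDF value of its intensity bin, so
    the output lies in [0, 1] and the mapping is monotone non-decreasing.
    """
    data = volume.data
    vmin, vmax = float(data.min()), float(data.max())
    if vmax == vmin:
        return ImageVolume(np.ones_like(data), volume.spacing)
    hist, edges = np.histogram(data, bins=bins, range=(vmin, vmax))
    cdf = np.cumsum(hist) / data.size
    idx = np.clip(
        ((data - vmin) / (vmax - vmin) * bins).astype(int), 0, bins - 1
    )
    return ImageVolume(cdf[idx], volume.spacing)


def gaussian_denoise(volume: ImageVolume, sigma_mm: float) -> ImageVolume:
    """Gaussian smoothing with a physical sigma; ``sigma_mm == 0`` is identity.

    Reflective boundary handling keeps the global mean exact for the
    symmetric kernel.
    """
    if sigma_mm < 0:
        raise ValueError("sigma_mm must be >= 0")
    if sigma_mm == 0:
        return volume
    sigma_vox = [sigma_mm / s for s in volume.spacing]
    out = ndimage.gaussian_filter(volume.data, sigma=sigma_vox, mode="reflect")
    return ImageVolume(out, volume.spacing)


def select_max_area_slices(
    volume: ImageVolume, mask: ROIMask, n_slices: int = 3
) -> tuple[ImageVolume, ROIMask]:
    """Pick the ``n_slices`` consecutive axial slices with maximal tumour area.

    The window maximising the summed in-mask voxel count wins; ties break
    toward the smallest starting index.  If the volume has fewer than
    ``n_slices`` slices, all are used with a warning.
    """
    if mask.voxel_count == 0:
        raise ValueError("mask is empty")
    nz = volume.shape[0]
    if nz < n_slices:
        warnings.warn(
            f"volume has {nz} slices < n_slices={n_slices}; using all", stacklevel=2
        )
        n_slices = nz
    areas = mask.data.sum(axis=(1, 2))
    window_sums = np.convolve(areas, np.ones(n_slices, dtype=int), mode="valid")
    start = int(np.argmax(window_sums))  # argmax takes the first maximum
    sl = slice(start, start + n_slices)
    return (
        ImageVolume(volume.data[sl].copy(), volume.spacing),
        ROIMask(mask.data[sl].copy(), mask.spacing),
    )


def resample_isotropic(
    volume: ImageVolume,
    mask: ROIMask,
    target_spacing: tuple[float, float, float],
) -> tuple[ImageVolume, ROIMask]:
    """Resample to a new grid: linear for the image, nearest for the mask."""
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target_spacing must be positive")
    if tuple(target_spacing) == volume.spacing:
        return volume.copy(), mask.copy()
    new_shape = tuple(
        max(1, int(round(n * old / new)))
        for n, old, new in zip(volume.shape, volume.spacing, target_spacing)
    )
    coords = np.meshgrid(
        *[
            np.clip(np.arange(n) * new / old, 0, old_n - 1)
            for n, new, old, old_n in zip(
                new_shape, target_spacing, volume.spacing, volume.shape
            )
        ],
        indexing="ij",
    )
    coords = np.stack(coords)
    new_data = ndimage.map_coordinates(volume.data, coords, order=1, mode="nearest")
    new_mask = ndimage.map_coordinates(
        mask.data.astype(np.uint8), coords, order=0, mode="nearest"
    ).astype(bool)
    ts = tuple(float(t) for t in target_spacing)
    return ImageVolume(new_data, ts), ROIMask(new_mask, ts)


def preprocess_sample(sample: LesionSample, config: PreprocessConfig) -> LesionSample:
    """Run the full fixed-order normalisation chain on one sample."""
    vol = window_level(sample.volume, config, sample.mask)
    if config.equalize:
        vol = equalize_histogram(vol, config.equalize_bins)
    vol = gaussian_denoise(vol, config.gauss_sigma_mm)
    slab_vol, slab_mask = select_max_area_slices(vol, sample.mask, config.n_slices)
    if config.rescale_max > 0:
        slab_vol = ImageVolume(slab_vol.data * config.rescale_max, slab_vol.spacing)
    return sample.with_(volume=slab_vol, mask=slab_mask, clean=None)
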