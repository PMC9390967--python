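"""Image/ROI perturbation families for feature-robustness testing.

Three families model multicentre acquisition variability:

* ``S`` - axial slice spacing: resampling to 1/2/3/5 mm section thickness;
* ``R`` - in-plane rotation by theta in {-30, -15, +15, +30} degrees about
  the mask centroid;
* ``Seg`` - ROI contour variation: morphological enlargement/shrinking by
  a physical radius (default 2 mm).

Perturbations never change the subject id or the response label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ImageVolume, LesionSample, ROIMask

__all__ = [
    "PerturbationSpec",
    "perturb_spacing",
    "perturb_rotation",
    "perturb_roi",
    "build_perturbation_set",
    "DEFAULT_SPECS",
]

DEFAULT_THICKNESSES_MM = (1.0, 2.0, 3.0, 5.0)
DEFAULT_ANGLES_DEG = (-30.0, -15.0, 15.0, 30.0)
DEFAULT_SEG_RADIUS_MM = 2.0


@dataclass
class PerturbationSpec:
    """One perturbation family with its parameter grid."""

    family: str  # "S" | "R" | "Seg"
    parameters: tuple = ()

    def __post_init__(self) -> None:
        if self.family not in ("S", "R", "Seg"):
            raise ValueError(f"unknown perturbation family {self.family!r}")
        if not self.parameters:
            defaults = {
                "S": DEFAULT_THICKNESSES_MM,
                "R": DEFAULT_ANGLES_DEG,
                "Seg": (("enlarge", DEFAULT_SEG_RADIUS_MM), ("shrink", DEFAULT_SEG_RADIUS_MM)),
            }
            self.parameters = defaults[self.family]


DEFAULT_SPECS = (
    PerturbationSpec("S"),
    PerturbationSpec("R"),
    PerturbationSpec("Seg"),
)


def perturb_spacing(sample: LesionSample, thickness_mm: float) -> LesionSample:
    """Resample the axial axis to the target slice thickness.

    Linear interpolation for the image, nearest-neighbour for the mask.
    """
    if thickness_mm <= 0:
        raise ValueError("thickness_mm must be > 0")
    tag = f"S:{thickness_mm:g}"
    old = sample.volume.spacing[0]
    if abs(thickness_mm - old) < 1e-12:
        return sample.with_(replicate=tag)
    nz = sample.volume.shape[0]
    extent = nz * old
    if extent < thickness_mm:
        raise ValueError(
            f"slab of extent {extent:g} mm is thinner than one {thickness_mm:g} mm slice"
        )
    new_nz = max(1, int(round(extent / thickness_mm)))
    z = np.clip(np.arange(new_nz) * thickness_mm / old, 0, nz - 1)
    vol = ndimage.map_coordinates(
        sample.volume.data,
        _axis0_coords(z, sample.volume.shape),
        order=1,
        mode="nearest",
    )
    mask = ndimage.map_coordinates(
        sample.mask.data.astype(np.uint8),
        _axis0_coords(z, sample.mask.shape),
        order=0,
        mode="nearest",
    ).astype(bool)
    spacing = (float(thickness_mm),) + sample.volume.spacing[1:]
    return sample.with_(
        volume=ImageVolume(vol, spacing),
        mask=ROIMask(mask, spacing),
        replicate=tag,
        clean=None,
    )


def _axis0_coords(z: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    zz, yy, xx = np.meshgrid(z, np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    return np.stack([zz, yy, xx])


def perturb_rotation(
    sample: LesionSample, theta_deg: float, background_hu: float | None = None
) -> LesionSample:
    """Rotate image and mask in the axial (y, x) plane about the mask centroid.

    Linear interpolation for the image (out-of-grid filled with the
    background level), nearest for the mask; the grid shape is unchanged.
    """
    tag = f"R:{theta_deg:+g}"
    if theta_deg % 360 == 0:
        return sample.with_(replicate=tag)
    if background_hu is None:
        background_hu = float(np.min(sample.volume.data))
    centroid = ndimage.center_of_mass(sample.mask.data)
    theta = np.deg2rad(theta_deg)
    c, s = np.cos(theta), np.sin(theta)
    # In-plane rotation acting on (z, y, x) index space.
    rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    offset = np.asarray(centroid) - rot @ np.asarray(centroid)
    vol = ndimage.affine_transform(
        sample.volume.data, rot, offset=offset, order=1, mode="constant",
        cval=background_hu,
    )
    mask = ndimage.affine_transform(
        sample.mask.data.astype(np.uint8), rot, offset=offset, order=0,
        mode="constant", cval=0,
    ).astype(bool)
    return sample.with_(
        volume=ImageVolume(vol, sample.volume.spacing),
        mask=ROIMask(mask, sample.mask.spacing),
        replicate=tag,
        clean=None,
    )


def _ball_structure(radius_mm: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Ellipsoidal structuring element of physical radius ``radius_mm``."""
    half = [int(np.floor(radius_mm / s)) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    return sum(g**2 for g in grids) <= radius_mm**2 + 1e-9


def perturb_roi(sample: LesionSample, mode: str, radius_mm: float = DEFAULT_SEG_RADIUS_MM) -> LesionSample:
    """Dilate (``enlarge``) or erode (``shrink``) the ROI; image untouched."""
    if mode not in ("enlarge", "shrink"):
        raise ValueError(f"mode must be 'enlarge' or 'shrink', got {mode!r}")
    if radius_mm <= 0:
        raise ValueError("radius_mm must be > 0")
    structure = _ball_structure(radius_mm, sample.mask.spacing)
    op = ndimage.binary_dilation if mode == "enlarge" else ndimage.binary_erosion
    new_mask = op(sample.mask.data, structure=structure)
    if not new_mask.any():
        raise ValueError(
            f"ROI shrink by {radius_mm} mm annihilates the mask of sample "
            f"{sample.subject_id!r}"
        )
    return sample.with_(
        mask=ROIMask(new_mask, sample.mask.spacing),
        replicate=f"Seg:{mode}",
    )


def build_perturbation_set(
    sample: LesionSample,
    specs: tuple[PerturbationSpec, ...] = DEFAULT_SPECS,
) -> dict[str, list[LesionSample]]:
    """Apply every admissible perturbation; returns family -> [original, *perturbed].

    With the default specs each family holds the original plus 4 (S),
    4 (R) and 2 (Seg) perturbed versions.
    """
    out: dict[str, list[LesionSample]] = {}
    for spec in specs:
        versions = [sample]
        if spec.family == "S":
            versions += [perturb_spacing(sample, t) for t in spec.parameters]
        elif spec.family == "R":
            versions += [perturb_rotation(sample, t) for t in spec.parameters]
        else:
            versions += [perturb_roi(sample, m, r) for m, r in spec.parameters]
        out[spec.family] = versions
    return out
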