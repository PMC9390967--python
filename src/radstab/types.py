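"""Core data containers shared by every pipeline stage.

Arrays are indexed ``(z, y, x)`` and ``spacing`` follows the same axis
order, in millimetres.  A :class:`LesionSample` bundles one image/mask
pair with its cohort metadata and is the unit record passed between
stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["ImageVolume", "ROIMask", "LesionSample"]


@dataclass
class ImageVolume:
    """A 3-D scalar grid in Hounsfield units with per-axis spacing (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing)


@dataclass
class ROIMask:
    """Binary grid aligned voxel-for-voxel with an :class:`ImageVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "ROIMask":
        return ROIMask(self.data.copy(), self.spacing)


@dataclass
class LesionSample:
    """One (volume, mask) pair with subject id, replicate tag and label.

    ``replicate`` is ``"baseline"`` for the original acquisition,
    ``"retest"`` for a test-retest replicate, or a perturbation tag such
    as ``"S:2.0"``, ``"R:+15"``, ``"Seg:enlarge"``.
    """

    volume: ImageVolume
    mask: ROIMask
    subject_id: str
    replicate: str = "baseline"
    label: int = 0
    # Noise-free lesion field, kept by the generator so that test-retest
    # replicates can re-draw acquisition noise on the same anatomy.
    clean: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.volume.shape != self.mask.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} != volume shape {self.volume.shape}"
            )
        if self.mask.voxel_count < 1:
            raise ValueError(f"mask of sample {self.subject_id!r} is empty")

    def with_(self, **changes) -> "LesionSample":
        """Return a shallow-copied sample with the given fields replaced."""
        return replace(self, **changes)
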