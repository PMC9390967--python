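"""Synthetic CT-lesion cohorts with test-retest replicate pairs.

Lesions are ellipsoids in a homogeneous lung-like background.  In-mask
texture is a Gaussian random field realised by convolving white noise
with a Gaussian kernel whose FWHM equals the requested correlation
length; independent acquisition noise is added everywhere.  All
randomness flows from a single cohort seed through documented
``numpy.random.SeedSequence`` spawns, so cohorts are byte-identical for
identical seeds.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .types import ImageVolume, LesionSample, ROIMask

__all__ = [
    "LesionParams",
    "CohortSpec",
    "generate_lesion",
    "generate_cohort",
    "generate_test_retest_pair",
    "write_cohort",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class LesionParams:
    """Geometry and intensity statistics of one synthetic lesion."""

    semiaxes_mm: tuple[float, float, float] = (8.0, 12.0, 12.0)
    center_mm: Optional[tuple[float, float, float]] = None
    mean_hu: float = 40.0
    texture_corr_mm: float = 3.0
    texture_sd_hu: float = 60.0
    noise_sd_hu: float = 10.0
    background_hu: float = -800.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes_mm):
            raise ValueError(f"semiaxes_mm must be positive, got {self.semiaxes_mm}")
        if self.texture_sd_hu < 0:
            raise ValueError("texture_sd_hu must be >= 0")
        if self.noise_sd_hu < 0:
            raise ValueError("noise_sd_hu must be >= 0")


@dataclass
class CohortSpec:
    """Counts, per-class lesion statistics and acquisition geometry."""

    n_responsive: int = 124
    n_unresponsive: int = 33
    responsive_params: LesionParams = field(
        default_factory=lambda: LesionParams(texture_corr_mm=2.0)
    )
    unresponsive_params: LesionParams = field(
        default_factory=lambda: LesionParams(texture_corr_mm=5.0)
    )
    spacing_mm: tuple[float, float, float] = (2.0, 0.75, 0.75)
    shape: tuple[int, int, int] = (16, 48, 48)
    jitter: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responsive < 0 or self.n_unresponsive < 0:
            raise ValueError("class counts must be non-negative")


def _gaussian_random_field(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    corr_mm: float,
    sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """White noise smoothed to correlation length ``corr_mm`` with SD ``sd``.

    The smoothing kernel has FWHM = corr_mm; the field is renormalised by
    the theoretical factor sqrt(sum k^2) so the marginal SD is exactly
    ``sd`` in expectation.
    """
    white = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    sigma_vox = [corr_mm * _FWHM_TO_SIGMA / s for s in spacing]
    if all(sv < 1e-6 for sv in sigma_vox):
        return sd * white
    smoothed = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="wrap")
    # Variance of (white * kernel) is sum(kernel^2); compute it from an impulse.
    impulse = np.zeros(shape)
    impulse[tuple(n // 2 for n in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma_vox, mode="wrap")
    norm = np.sqrt(np.sum(kernel**2))
    return sd * smoothed / norm


def _ellipsoid_mask(
    shape: tuple[int, int, int],
    spacing: Sequence[float],
    semiaxes_mm: Sequence[float],
    center_mm: Sequence[float],
) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center_mm, semiaxes_mm))
    return r2 <= 1.0


def generate_lesion(
    params: LesionParams,
    spacing: tuple[float, float, float] = (2.0, 0.75, 0.75),
    shape: tuple[int, int, int] = (16, 48, 48),
    seed: "int | np.random.SeedSequence" = 0,
    subject_id: str = "subject-0",
    label: int = 0,
) -> LesionSample:
    """Generate one ellipsoidal lesion in a noisy background volume.

    Raises
    ------
    ValueError
        If the ellipsoid does not fit inside the grid along some axis;
        the message names the offending axis.
    """
    axis_names = "zyx"
    center = params.center_mm
    if center is None:
        center = tuple((n - 1) * s / 2.0 for n, s in zip(shape, spacing))
    for i, (a, c, n, s) in enumerate(zip(params.semiaxes_mm, center, shape, spacing)):
        extent = (n - 1) * s
        if c - a < 0 or c + a > extent:
            raise ValueError(
                f"ellipsoid exceeds the grid along axis {axis_names[i]!r}: "
                f"center {c} mm +/- semiaxis {a} mm vs extent [0, {extent}] mm"
            )
    rng = np.random.default_rng(seed)
    mask = _ellipsoid_mask(shape, spacing, params.semiaxes_mm, center)
    texture = _gaussian_random_field(
        shape, spacing, params.texture_corr_mm, params.texture_sd_hu, rng
    )
    clean = np.where(mask, params.mean_hu + texture, params.background_hu)
    noise = (
        rng.standard_normal(shape) * params.noise_sd_hu
        if params.noise_sd_hu > 0
        else 0.0
    )
    data = clean + noise
    return LesionSample(
        volume=ImageVolume(data, spacing),
        mask=ROIMask(mask, spacing),
        subject_id=subject_id,
        replicate="baseline",
        label=label,
        clean=clean,
    )


def _jittered_params(
    base: LesionParams, jitter: float, rng: np.random.Generator
) -> LesionParams:
    """Per-subject geometry/intensity jitter around the class parameters."""
    if jitter <= 0:
        return base
    factors = rng.uniform(1.0 - jitter, 1.0 + jitter, size=3)
    semiaxes = tuple(a * f for a, f in zip(base.semiaxes_mm, factors))
    mean_hu = base.mean_hu + rng.uniform(-jitter, jitter) * 100.0
    return replace(base, semiaxes_mm=semiaxes, mean_hu=mean_hu)


def _subject_seed(cohort_seed: int, index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=cohort_seed, spawn_key=(index,))


def generate_cohort(spec: CohortSpec) -> list[LesionSample]:
    """Generate ``n_responsive + n_unresponsive`` labelled lesion samples.

    Labels: 1 = responsive, 0 = unresponsive; responsive subjects come
    first.  Subject ``i`` derives all of its randomness from
    ``SeedSequence(entropy=spec.seed, spawn_key=(i,))``.
    """
    samples: list[LesionSample] = []
    labels = [1] * spec.n_responsive + [0] * spec.n_unresponsive
    for i, label in enumerate(labels):
        ss = _subject_seed(spec.seed, i)
        jitter_rng = np.random.default_rng(ss.spawn(1)[0])
        base = spec.responsive_params if label == 1 else spec.unresponsive_params
        params = _jittered_params(base, spec.jitter, jitter_rng)
        lesion_seed = ss  # generate_lesion re-wraps into default_rng
        sample = generate_lesion(
            params,
            spacing=spec.spacing_mm,
            shape=spec.shape,
            seed=lesion_seed,
            subject_id=f"subject-{i:03d}",
            label=label,
        )
        samples.append(sample)
    return samples


def generate_test_retest_pair(
    sample: LesionSample,
    seed: int = 0,
    noise_sd_hu: float = 10.0,
    max_shift_voxels: float = 1.0,
) -> tuple[LesionSample, LesionSample]:
    """Return (baseline, retest) replicates of one lesion.

    The retest keeps the underlying noise-free lesion field, re-draws
    i.i.d. acquisition noise, and applies a small random rigid shift
    drawn uniformly in [-max_shift_voxels, +max_shift_voxels] per axis
    (linear interpolation for the image, nearest for the mask).
    """
    rng = np.random.default_rng(seed)
    clean = sample.clean if sample.clean is not None else sample.volume.data
    shift = (
        rng.uniform(-max_shift_voxels, max_shift_voxels, size=3)
        if max_shift_voxels > 0
        else np.zeros(3)
    )
    shifted = ndimage.shift(clean, shift, order=1, mode="nearest")
    mask = ndimage.shift(
        sample.mask.data.astype(np.float64), shift, order=0, mode="constant", cval=0.0
    ).astype(bool)
    if not mask.any():  # shift pushed a tiny mask out; keep original
        mask = sample.mask.data.copy()
    noise = rng.standard_normal(clean.shape) * noise_sd_hu if noise_sd_hu > 0 else 0.0
    baseline = sample.with_(replicate="baseline")
    retest = LesionSample(
        volume=ImageVolume(shifted + noise, sample.volume.spacing),
        mask=ROIMask(mask, sample.mask.spacing),
        subject_id=sample.subject_id,
        replicate="retest",
        label=sample.label,
        clean=shifted,
    )
    return baseline, retest


def write_cohort(samples: Sequence[LesionSample], out_dir: str | Path) -> Path:
    """Write NIfTI volume/mask pairs plus a manifest CSV; returns manifest path."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "cohort.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "replicate", "label", "volume", "mask"])
        for s in samples:
            stem = f"{s.subject_id}_{s.replicate.replace(':', '-')}"
            affine = np.diag(list(s.volume.spacing[::-1]) + [1.0])
            vol_path = out / f"{stem}_image.nii.gz"
            mask_path = out / f"{stem}_mask.nii.gz"
            # NIfTI is (x, y, z); our arrays are (z, y, x).
            nib.save(nib.Nifti1Image(s.volume.data.T, affine), vol_path)
            nib.save(
                nib.Nifti1Image(s.mask.data.T.astype(np.uint8), affine), mask_path
            )
            writer.writerow(
                [s.subject_id, s.replicate, s.label, vol_path.name, mask_path.name]
            )
    return manifest
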