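"""3-D shape descriptors of the ROI (14 features).

Surface quantities come from a marching-cubes mesh of the zero-padded
mask at iso-level 0.5 (triangle-sum area, divergence-theorem volume);
axis lengths come from the eigenvalues of the physical-coordinate
covariance of the in-mask voxel centres (population convention,
``lambda`` sorted descending, axis length ``4 * sqrt(lambda)``).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import marching_cubes

__all__ = ["SHAPE_NAMES", "shape_features", "mesh_surface"]

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


def mesh_surface(
    mask: np.ndarray, spacing: tuple[float, float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Marching-cubes mesh (vertices in mm, faces) of the padded mask."""
    padded = np.pad(mask.astype(np.float64), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts - np.asarray(spacing)  # undo the 1-voxel pad offset
    return verts, faces


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Exact diameter via the convex hull (the maximum is attained there)."""
    if len(points) < 2:
        return 0.0
    pts = points
    if len(points) > 16:
        try:
            pts = points[ConvexHull(points).vertices]
        except Exception:  # degenerate (coplanar/collinear) input
            pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def shape_features(
    mask: np.ndarray, spacing: tuple[float, float, float]
) -> dict[str, float]:
    mask = mask.astype(bool)
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError("mask is empty")
    voxel_volume = float(np.prod(spacing)) * n_vox

    verts, faces = mesh_surface(mask, spacing)
    tri = verts[faces]  # (n_faces, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = float(0.5 * np.sum(np.linalg.norm(cross, axis=1)))
    mesh_volume = float(
        abs(np.sum(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))))
        / 6.0
    )

    sphericity = (36.0 * np.pi * mesh_volume**2) ** (1.0 / 3.0) / area if area > 0 else 0.0

    # Physical coordinates of voxel centres for the axis-length features.
    coords = np.argwhere(mask) * np.asarray(spacing)
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / n_vox  # population covariance
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major, minor, least = (4.0 * np.sqrt(eig)).tolist()
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    d3 = _max_pairwise_distance(verts)
    d_slice = _max_pairwise_distance(verts[:, 1:])  # (y, x) plane
    d_column = _max_pairwise_distance(verts[:, [0, 1]])  # (z, y) plane
    d_row = _max_pairwise_distance(verts[:, [0, 2]])  # (z, x) plane

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_volume if mesh_volume > 0 else 0.0,
        "Sphericity": float(sphericity),
        "Maximum3DDiameter": d3,
        "Maximum2DDiameterSlice": d_slice,
        "Maximum2DDiameterColumn": d_column,
        "Maximum2DDiameterRow": d_row,
        "MajorAxisLength": major,
        "MinorAxisLength": minor,
        "LeastAxisLength": least,
        "Elongation": elongation,
        "Flatness": flatness,
    }
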