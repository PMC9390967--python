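"""Texture-matrix builders on a discretised grey-level map.

All builders take an integer level map (0 outside the ROI, 1..Ng
inside) plus the boolean mask.  Directional matrices (GLCM, GLRLM) use
the 13 unique 3-D directions of the 26-neighbourhood and are
direction-averaged; GLSZM zones and GLDM/NGTDM neighbourhoods use full
26-connectivity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS_13",
    "OFFSETS_26",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
]


def _unique_directions() -> list[tuple[int, int, int]]:
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                d = (dz, dy, dx)
                if d == (0, 0, 0):
                    continue
                if (-dz, -dy, -dx) in dirs:
                    continue
                dirs.append(d)
    return dirs


DIRECTIONS_13 = tuple(_unique_directions())
OFFSETS_26 = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
)


def _pair_slices(shape, d):
    """Index slices (base, neighbour) aligning voxel p with p + d."""
    base, neigh = [], []
    for n, di in zip(shape, d):
        base.append(slice(max(0, -di), n - max(0, di)))
        neigh.append(slice(max(0, di), n - max(0, -di)))
    return tuple(base), tuple(neigh)


def glcm(
    levels: np.ndarray, mask: np.ndarray, ng: int, distance: int = 1
) -> np.ndarray:
    """Symmetric, direction-averaged grey-level co-occurrence matrix.

    Pairs are counted per direction at the given Chebyshev distance,
    symmetrised, normalised per direction, then averaged over the
    directions that contain at least one pair.
    """
    mask = mask.astype(bool)
    acc = np.zeros((ng, ng))
    n_dirs = 0
    for d in DIRECTIONS_13:
        dd = tuple(di * distance for di in d)
        b, nb = _pair_slices(levels.shape, dd)
        valid = mask[b] & mask[nb]
        if not valid.any():
            continue
        l1 = levels[b][valid] - 1
        l2 = levels[nb][valid] - 1
        counts = np.bincount(l1 * ng + l2, minlength=ng * ng).reshape(ng, ng)
        counts = counts + counts.T  # symmetrise
        acc += counts / counts.sum()
        n_dirs += 1
    if n_dirs == 0:  # single in-mask voxel: all mass at its level
        lv = int(levels[mask][0]) - 1
        acc[lv, lv] = 1.0
        n_dirs = 1
    return acc / n_dirs


def glrlm(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Direction-averaged grey-level run-length matrix (counts / 13)."""
    mask = mask.astype(bool)
    shape = levels.shape
    max_len = int(np.ceil(np.sqrt(3) * max(shape))) + 1
    acc = np.zeros((ng, max_len))
    for d in DIRECTIONS_13:
        # A run starts where the previous voxel along d is not a same-level
        # in-mask voxel.
        b, nb = _pair_slices(shape, tuple(-di for di in d))
        same_prev = np.zeros(shape, dtype=bool)
        same_prev[b] = mask[b] & mask[nb] & (levels[b] == levels[nb])
        starts = mask & ~same_prev
        zs, ys, xs = np.nonzero(starts)
        lev = levels[zs, ys, xs]
        lengths = np.ones(zs.size, dtype=np.int64)
        cz, cy, cx = zs.copy(), ys.copy(), xs.copy()
        idx = np.arange(zs.size)
        while idx.size:
            z2, y2, x2 = cz[idx] + d[0], cy[idx] + d[1], cx[idx] + d[2]
            inb = (
                (z2 >= 0) & (z2 < shape[0])
                & (y2 >= 0) & (y2 < shape[1])
                & (x2 >= 0) & (x2 < shape[2])
            )
            ok = inb.copy()
            if inb.any():
                zi, yi, xi = z2[inb], y2[inb], x2[inb]
                ok[inb] = mask[zi, yi, xi] & (levels[zi, yi, xi] == lev[idx][inb])
            keep = idx[ok]
            lengths[keep] += 1
            cz[keep], cy[keep], cx[keep] = z2[ok], y2[ok], x2[ok]
            idx = keep
        np.add.at(acc, (lev - 1, lengths - 1), 1.0)
    acc /= len(DIRECTIONS_13)
    last = np.nonzero(acc.sum(axis=0))[0]
    return acc[:, : last[-1] + 1] if last.size else acc[:, :1]


def glszm(levels: np.ndarray, mask: np.ndarray, ng: int) -> np.ndarray:
    """Grey-level size-zone matrix: 26-connected equal-level zones."""
    mask = mask.astype(bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    zone_rows: list[int] = []
    zone_sizes: list[int] = []
    for lv in np.unique(levels[mask]):
        lab, n_zones = ndimage.label((levels == lv) & mask, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        zone_rows.extend([lv - 1] * n_zones)
        zone_sizes.extend(sizes.tolist())
    max_size = max(zone_sizes)
    out = np.zeros((ng, max_size))
    np.add.at(out, (np.array(zone_rows), np.array(zone_sizes) - 1), 1.0)
    return out


def gldm(
    levels: np.ndarray, mask: np.ndarray, ng: int, alpha: int = 0
) -> np.ndarray:
    """Grey-level dependence matrix.

    The dependence size of a voxel is 1 (itself) plus the number of
    26-neighbours inside the mask whose level differs by at most
    ``alpha``.
    """
    mask = mask.astype(bool)
    dep = np.zeros(levels.shape, dtype=np.int64)
    for d in OFFSETS_26:
        b, nb = _pair_slices(levels.shape, d)
        dependent = mask[b] & mask[nb] & (np.abs(levels[b] - levels[nb]) <= alpha)
        dep[b] += dependent
    dep_in = dep[mask] + 1  # centre voxel counts
    lev_in = levels[mask]
    out = np.zeros((ng, int(dep_in.max())))
    np.add.at(out, (lev_in - 1, dep_in - 1), 1.0)
    return out


def ngtdm(
    levels: np.ndarray, mask: np.ndarray, ng: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbourhood grey-tone difference matrix.

    Returns ``(n_i, p_i, s_i)`` over levels ``i = 1..Ng``: voxel counts,
    probabilities and summed absolute differences from the mean level of
    the in-mask 26-neighbourhood.  Voxels with no in-mask neighbour are
    excluded from the counts.
    """
    mask = mask.astype(bool)
    nbr_sum = np.zeros(levels.shape, dtype=np.float64)
    nbr_cnt = np.zeros(levels.shape, dtype=np.int64)
    lv = np.where(mask, levels, 0).astype(np.float64)
    for d in OFFSETS_26:
        b, nb = _pair_slices(levels.shape, d)
        nbr_sum[b] += lv[nb]
        nbr_cnt[b] += mask[nb]
    valid = mask & (nbr_cnt > 0)
    mean_nbr = np.zeros(levels.shape)
    mean_nbr[valid] = nbr_sum[valid] / nbr_cnt[valid]
    diffs = np.abs(levels[valid] - mean_nbr[valid])
    lev_valid = levels[valid]
    n = np.bincount(lev_valid - 1, minlength=ng).astype(np.float64)
    s = np.bincount(lev_valid - 1, weights=diffs, minlength=ng)
    total = n.sum()
    p = n / total if total > 0 else n
    return n, p, s
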