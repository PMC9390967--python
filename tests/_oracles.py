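"""Independent brute-force reference implementations used as test oracles.

Everything here is written as a direct, naive transcription of the
defining formulas - explicit Python loops over voxels, dictionaries for
matrices - and deliberately shares no code with the package
implementation it checks (the marching-cubes mesh generation is the one
shared primitive; all arithmetic downstream of it is recomputed here).
Keep inputs small: these are O(voxels * neighbourhood) pure-Python loops.
"""

from __future__ import annotations

import math

import numpy as np

EPS = np.spacing(1.0)

ALL_DIRECTIONS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
HALF_DIRECTIONS = []
for d in ALL_DIRECTIONS:
    if tuple(-c for c in d) not in HALF_DIRECTIONS:
        HALF_DIRECTIONS.append(d)


def _in(shape, p):
    return all(0 <= c < n for c, n in zip(p, shape))


def _voxels(mask):
    return [tuple(p) for p in np.argwhere(mask)]


# ------------------------------------------------------------------ builders


def ref_discretize_fbw(volume, mask, width):
    vals = volume[mask]
    vmin = vals.min()
    levels = np.zeros(volume.shape, dtype=int)
    for p in _voxels(mask):
        levels[p] = int(math.floor((volume[p] - vmin) / width)) + 1
    return levels, int(levels.max())


def ref_glcm(levels, mask, ng, distance=1):
    """Per-direction normalised symmetric co-occurrence, direction-averaged."""
    shape = levels.shape
    acc = np.zeros((ng, ng))
    used = 0
    for d in HALF_DIRECTIONS:
        counts = np.zeros((ng, ng))
        for p in _voxels(mask):
            q = tuple(c + dd * distance for c, dd in zip(p, d))
            if _in(shape, q) and mask[q]:
                i, j = levels[p] - 1, levels[q] - 1
                counts[i, j] += 1
                counts[j, i] += 1
        if counts.sum() > 0:
            acc += counts / counts.sum()
            used += 1
    return acc / used


def ref_glrlm(levels, mask, ng):
    """Runs enumerated by walking each line from its start; counts / 13."""
    shape = levels.shape
    runs = {}  # (level, length) -> count
    for d in HALF_DIRECTIONS:
        for p in _voxels(mask):
            prev = tuple(c - dd for c, dd in zip(p, d))
            if _in(shape, prev) and mask[prev] and levels[prev] == levels[p]:
                continue  # not a run start
            length = 1
            q = tuple(c + dd for c, dd in zip(p, d))
            while _in(shape, q) and mask[q] and levels[q] == levels[p]:
                length += 1
                q = tuple(c + dd for c, dd in zip(q, d))
            key = (levels[p], length)
            runs[key] = runs.get(key, 0) + 1
    max_len = max(length for (_, length) in runs)
    P = np.zeros((ng, max_len))
    for (lv, length), count in runs.items():
        P[lv - 1, length - 1] = count / len(HALF_DIRECTIONS)
    return P


def ref_glszm(levels, mask, ng):
    """Zones by breadth-first flood fill over the 26-neighbourhood."""
    shape = levels.shape
    seen = set()
    zones = []
    for start in _voxels(mask):
        if start in seen:
            continue
        lv = levels[start]
        stack, zone = [start], []
        seen.add(start)
        while stack:
            p = stack.pop()
            zone.append(p)
            for d in ALL_DIRECTIONS:
                q = tuple(c + dd for c, dd in zip(p, d))
                if (
                    q not in seen
                    and _in(shape, q)
                    and mask[q]
                    and levels[q] == lv
                ):
                    seen.add(q)
                    stack.append(q)
        zones.append((lv, len(zone)))
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for lv, size in zones:
        P[lv - 1, size - 1] += 1
    return P


def ref_gldm(levels, mask, ng, alpha=0):
    shape = levels.shape
    entries = []
    for p in _voxels(mask):
        dep = 1  # the centre voxel
        for d in ALL_DIRECTIONS:
            q = tuple(c + dd for c, dd in zip(p, d))
            if _in(shape, q) and mask[q] and abs(levels[q] - levels[p]) <= alpha:
                dep += 1
        entries.append((levels[p], dep))
    max_dep = max(dep for _, dep in entries)
    P = np.zeros((ng, max_dep))
    for lv, dep in entries:
        P[lv - 1, dep - 1] += 1
    return P


def ref_ngtdm(levels, mask, ng):
    shape = levels.shape
    n = np.zeros(ng)
    s = np.zeros(ng)
    for p in _voxels(mask):
        nbrs = []
        for d in ALL_DIRECTIONS:
            q = tuple(c + dd for c, dd in zip(p, d))
            if _in(shape, q) and mask[q]:
                nbrs.append(levels[q])
        if not nbrs:
            continue
        i = levels[p]
        n[i - 1] += 1
        s[i - 1] += abs(i - sum(nbrs) / len(nbrs))
    p_ = n / n.sum() if n.sum() > 0 else n
    return n, p_, s


# ------------------------------------------------------------------ features


def _percentile(sorted_vals, q):
    """Linear-interpolation percentile, transcribed from the definition."""
    n = len(sorted_vals)
    pos = (n - 1) * q / 100.0
    lo = int(math.floor(pos))
    hi = min(lo + 1, n - 1)
    frac = pos - lo
    return sorted_vals[lo] * (1 - frac) + sorted_vals[hi] * frac


def ref_firstorder(values, voxel_volume, bin_width):
    x = sorted(float(v) for v in values)
    n = len(x)
    mean = sum(x) / n
    energy = sum(v * v for v in x)
    p10 = _percentile(x, 10)
    p25 = _percentile(x, 25)
    p50 = _percentile(x, 50)
    p75 = _percentile(x, 75)
    p90 = _percentile(x, 90)
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust) if robust else 0.0
    var = sum((v - mean) ** 2 for v in x) / n
    skew = (
        (sum((v - mean) ** 3 for v in x) / n) / var**1.5 if var > 0 else 0.0
    )
    kurt = (sum((v - mean) ** 4 for v in x) / n) / var**2 if var > 0 else 0.0
    vmin = x[0]
    hist = {}
    for v in x:
        b = int(math.floor((v - vmin) / bin_width))
        hist[b] = hist.get(b, 0) + 1
    probs = [c / n for c in hist.values()]
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": -sum(p * math.log2(p) for p in probs),
        "Minimum": x[0],
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": x[-1],
        "Mean": mean,
        "Median": p50,
        "InterquartileRange": p75 - p25,
        "Range": x[-1] - x[0],
        "MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "RobustMeanAbsoluteDeviation": (
            sum(abs(v - rmean) for v in robust) / len(robust) if robust else 0.0
        ),
        "RootMeanSquared": math.sqrt(energy / n),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": sum(p * p for p in probs),
    }


def ref_glcm_features(P):
    ng = P.shape[0]

    def rng1():
        return range(1, ng + 1)

    px = [sum(P[i - 1, j - 1] for j in rng1()) for i in rng1()]
    mu = sum(i * px[i - 1] for i in rng1())
    sig2 = sum((i - mu) ** 2 * px[i - 1] for i in rng1())
    p_diff = [0.0] * ng
    p_sum = [0.0] * (2 * ng + 1)
    for i in rng1():
        for j in rng1():
            p_diff[abs(i - j)] += P[i - 1, j - 1]
            p_sum[i + j] += P[i - 1, j - 1]
    hx = -sum(p * math.log2(p) for p in px if p > 0)
    hxy = -sum(
        P[i - 1, j - 1] * math.log2(P[i - 1, j - 1])
        for i in rng1()
        for j in rng1()
        if P[i - 1, j - 1] > 0
    )
    hxy1 = -sum(
        P[i - 1, j - 1] * math.log2(px[i - 1] * px[j - 1] + EPS)
        for i in rng1()
        for j in rng1()
    )
    hxy2 = -sum(
        px[i - 1] * px[j - 1] * math.log2(px[i - 1] * px[j - 1])
        for i in rng1()
        for j in rng1()
        if px[i - 1] * px[j - 1] > 0
    )
    da = sum(k * p_diff[k] for k in range(ng))
    occupied = [i for i in rng1() if px[i - 1] > 0]
    if len(occupied) >= 2:
        Q = np.zeros((len(occupied), len(occupied)))
        for a, i in enumerate(occupied):
            for b, j in enumerate(occupied):
                Q[a, b] = sum(
                    P[i - 1, k - 1] * P[j - 1, k - 1] / (px[i - 1] * px[k - 1])
                    for k in occupied
                )
        eig = sorted(np.linalg.eigvals(Q).real)
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 1.0
    return {
        "Autocorrelation": sum(i * j * P[i - 1, j - 1] for i in rng1() for j in rng1()),
        "JointAverage": mu,
        "ClusterProminence": sum(
            (i + j - 2 * mu) ** 4 * P[i - 1, j - 1] for i in rng1() for j in rng1()
        ),
        "ClusterShade": sum(
            (i + j - 2 * mu) ** 3 * P[i - 1, j - 1] for i in rng1() for j in rng1()
        ),
        "ClusterTendency": sum(
            (i + j - 2 * mu) ** 2 * P[i - 1, j - 1] for i in rng1() for j in rng1()
        ),
        "Contrast": sum(
            (i - j) ** 2 * P[i - 1, j - 1] for i in rng1() for j in rng1()
        ),
        "Correlation": (
            (
                sum(i * j * P[i - 1, j - 1] for i in rng1() for j in rng1())
                - mu * mu
            )
            / sig2
            if sig2 > 0
            else 1.0
        ),
        "DifferenceAverage": da,
        "DifferenceEntropy": -sum(
            p * math.log2(p) for p in p_diff if p > 0
        ),
        "DifferenceVariance": sum(
            (k - da) ** 2 * p_diff[k] for k in range(ng)
        ),
        "JointEnergy": sum(
            P[i - 1, j - 1] ** 2 for i in rng1() for j in rng1()
        ),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))),
        "Idm": sum(
            P[i - 1, j - 1] / (1 + (i - j) ** 2) for i in rng1() for j in rng1()
        ),
        "Idmn": sum(
            P[i - 1, j - 1] / (1 + ((i - j) / ng) ** 2)
            for i in rng1()
            for j in rng1()
        ),
        "Id": sum(
            P[i - 1, j - 1] / (1 + abs(i - j)) for i in rng1() for j in rng1()
        ),
        "Idn": sum(
            P[i - 1, j - 1] / (1 + abs(i - j) / ng) for i in rng1() for j in rng1()
        ),
        "InverseVariance": sum(
            P[i - 1, j - 1] / (i - j) ** 2
            for i in rng1()
            for j in rng1()
            if i != j
        ),
        "MaximumProbability": float(P.max()),
        "SumAverage": sum(k * p_sum[k] for k in range(2, 2 * ng + 1)),
        "SumEntropy": -sum(p * math.log2(p) for p in p_sum if p > 0),
        "SumSquares": sum(
            (i - mu) ** 2 * P[i - 1, j - 1] for i in rng1() for j in rng1()
        ),
        "MCC": mcc,
    }


def _ref_run_style(P, n_voxels):
    ng, ns = P.shape
    nz = P.sum()
    out = {}
    out["small"] = sum(
        P[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / nz
    out["large"] = sum(
        P[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / nz
    out["gln"] = sum(P[i, :].sum() ** 2 for i in range(ng)) / nz
    out["glnn"] = out["gln"] / nz
    out["sn"] = sum(P[:, j].sum() ** 2 for j in range(ns)) / nz
    out["snn"] = out["sn"] / nz
    out["pct"] = nz / n_voxels
    mu_i = sum((i + 1) * P[i, :].sum() / nz for i in range(ng))
    mu_j = sum((j + 1) * P[:, j].sum() / nz for j in range(ns))
    out["glv"] = sum(
        P[i, j] / nz * (i + 1 - mu_i) ** 2 for i in range(ng) for j in range(ns)
    )
    out["sv"] = sum(
        P[i, j] / nz * (j + 1 - mu_j) ** 2 for i in range(ng) for j in range(ns)
    )
    out["entropy"] = -sum(
        P[i, j] / nz * math.log2(P[i, j] / nz)
        for i in range(ng)
        for j in range(ns)
        if P[i, j] > 0
    )
    out["lgl"] = sum(
        P[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / nz
    out["hgl"] = sum(
        P[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(ns)
    ) / nz
    out["slgl"] = sum(
        P[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
        for i in range(ng)
        for j in range(ns)
    ) / nz
    out["shgl"] = sum(
        P[i, j] * (i + 1) ** 2 / (j + 1) ** 2
        for i in range(ng)
        for j in range(ns)
    ) / nz
    out["llgl"] = sum(
        P[i, j] * (j + 1) ** 2 / (i + 1) ** 2
        for i in range(ng)
        for j in range(ns)
    ) / nz
    out["lhgl"] = sum(
        P[i, j] * (i + 1) ** 2 * (j + 1) ** 2
        for i in range(ng)
        for j in range(ns)
    ) / nz
    return out


def ref_glrlm_features(P, n_voxels):
    b = _ref_run_style(P, n_voxels)
    return {
        "ShortRunEmphasis": b["small"],
        "LongRunEmphasis": b["large"],
        "GrayLevelNonUniformity": b["gln"],
        "GrayLevelNonUniformityNormalized": b["glnn"],
        "RunLengthNonUniformity": b["sn"],
        "RunLengthNonUniformityNormalized": b["snn"],
        "RunPercentage": b["pct"],
        "GrayLevelVariance": b["glv"],
        "RunVariance": b["sv"],
        "RunEntropy": b["entropy"],
        "LowGrayLevelRunEmphasis": b["lgl"],
        "HighGrayLevelRunEmphasis": b["hgl"],
        "ShortRunLowGrayLevelEmphasis": b["slgl"],
        "ShortRunHighGrayLevelEmphasis": b["shgl"],
        "LongRunLowGrayLevelEmphasis": b["llgl"],
        "LongRunHighGrayLevelEmphasis": b["lhgl"],
    }


def ref_glszm_features(P, n_voxels):
    b = _ref_run_style(P, n_voxels)
    return {
        "SmallAreaEmphasis": b["small"],
        "LargeAreaEmphasis": b["large"],
        "GrayLevelNonUniformity": b["gln"],
        "GrayLevelNonUniformityNormalized": b["glnn"],
        "SizeZoneNonUniformity": b["sn"],
        "SizeZoneNonUniformityNormalized": b["snn"],
        "ZonePercentage": b["pct"],
        "GrayLevelVariance": b["glv"],
        "ZoneVariance": b["sv"],
        "ZoneEntropy": b["entropy"],
        "LowGrayLevelZoneEmphasis": b["lgl"],
        "HighGrayLevelZoneEmphasis": b["hgl"],
        "SmallAreaLowGrayLevelEmphasis": b["slgl"],
        "SmallAreaHighGrayLevelEmphasis": b["shgl"],
        "LargeAreaLowGrayLevelEmphasis": b["llgl"],
        "LargeAreaHighGrayLevelEmphasis": b["lhgl"],
    }


def ref_gldm_features(P, n_voxels):
    b = _ref_run_style(P, n_voxels)
    return {
        "SmallDependenceEmphasis": b["small"],
        "LargeDependenceEmphasis": b["large"],
        "GrayLevelNonUniformity": b["gln"],
        "DependenceNonUniformity": b["sn"],
        "DependenceNonUniformityNormalized": b["snn"],
        "GrayLevelVariance": b["glv"],
        "DependenceVariance": b["sv"],
        "DependenceEntropy": b["entropy"],
        "LowGrayLevelEmphasis": b["lgl"],
        "HighGrayLevelEmphasis": b["hgl"],
        "SmallDependenceLowGrayLevelEmphasis": b["slgl"],
        "SmallDependenceHighGrayLevelEmphasis": b["shgl"],
        "LargeDependenceLowGrayLevelEmphasis": b["llgl"],
        "LargeDependenceHighGrayLevelEmphasis": b["lhgl"],
    }


def ref_ngtdm_features(n, p, s):
    ng = len(n)
    nv = n.sum()
    occ = [i for i in range(ng) if p[i] > 0]
    sum_ps = sum(p[i] * s[i] for i in range(ng))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    ngp = len(occ)
    if ngp > 1:
        contrast = (
            sum(
                p[i] * p[j] * (i - j) ** 2 for i in occ for j in occ
            )
            / (ngp * (ngp - 1))
            * (s.sum() / nv)
        )
        busy_den = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in occ for j in occ
        )
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j)
                * (p[i] * s[i] + p[j] * s[j])
                / (p[i] + p[j])
                for i in occ
                for j in occ
            )
            / nv
        )
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in occ for j in occ) / s.sum()
            if s.sum() > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


def ref_shape_features(mask, spacing):
    """Shape oracle: shares the marching-cubes mesh primitive, recomputes
    every downstream quantity independently (loops, explicit formulas)."""
    from radstab.features.shape import mesh_surface

    verts, faces = mesh_surface(mask, spacing)
    area = 0.0
    vol6 = 0.0
    for f in faces:
        a, b, c = verts[f[0]], verts[f[1]], verts[f[2]]
        ab, ac = b - a, c - a
        cross = (
            ab[1] * ac[2] - ab[2] * ac[1],
            ab[2] * ac[0] - ab[0] * ac[2],
            ab[0] * ac[1] - ab[1] * ac[0],
        )
        area += 0.5 * math.sqrt(sum(x * x for x in cross))
        vol6 += (
            a[0] * (b[1] * c[2] - b[2] * c[1])
            - a[1] * (b[0] * c[2] - b[2] * c[0])
            + a[2] * (b[0] * c[1] - b[1] * c[0])
        )
    mesh_volume = abs(vol6) / 6.0
    n_vox = int(mask.sum())
    voxel_volume = n_vox * spacing[0] * spacing[1] * spacing[2]

    coords = np.argwhere(mask).astype(float) * np.asarray(spacing)
    centred = coords - coords.mean(axis=0)
    cov = np.zeros((3, 3))
    for row in centred:
        cov += np.outer(row, row)
    cov /= n_vox
    eig = sorted(np.linalg.eigvalsh(cov), reverse=True)
    eig = [max(0.0, e) for e in eig]

    def max_dist(points):
        best = 0.0
        pts = np.asarray(points)
        for i in range(len(pts)):
            d2 = np.sum((pts[i + 1 :] - pts[i]) ** 2, axis=1)
            if d2.size:
                best = max(best, float(d2.max()))
        return math.sqrt(best)

    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": area,
        "SurfaceVolumeRatio": area / mesh_volume,
        "Sphericity": (36 * math.pi * mesh_volume**2) ** (1 / 3) / area,
        "Maximum3DDiameter": max_dist(verts),
        "Maximum2DDiameterSlice": max_dist(verts[:, 1:]),
        "Maximum2DDiameterColumn": max_dist(verts[:, [0, 1]]),
        "Maximum2DDiameterRow": max_dist(verts[:, [0, 2]]),
        "MajorAxisLength": 4 * math.sqrt(eig[0]),
        "MinorAxisLength": 4 * math.sqrt(eig[1]),
        "LeastAxisLength": 4 * math.sqrt(eig[2]),
        "Elongation": math.sqrt(eig[1] / eig[0]),
        "Flatness": math.sqrt(eig[2] / eig[0]),
    }


def ref_extract_107(volume, mask, spacing, bin_width=25.0):
    """All 107 original-image features via the brute-force route."""
    levels, ng = ref_discretize_fbw(volume, mask, bin_width)
    n_vox = int(mask.sum())
    vv = spacing[0] * spacing[1] * spacing[2]
    out = {}
    for k, v in ref_shape_features(mask, spacing).items():
        out[f"original_shape_{k}"] = v
    for k, v in ref_firstorder(volume[mask], vv, bin_width).items():
        out[f"original_firstorder_{k}"] = v
    for k, v in ref_glcm_features(ref_glcm(levels, mask, ng)).items():
        out[f"original_glcm_{k}"] = v
    for k, v in ref_glrlm_features(ref_glrlm(levels, mask, ng), n_vox).items():
        out[f"original_glrlm_{k}"] = v
    for k, v in ref_glszm_features(ref_glszm(levels, mask, ng), n_vox).items():
        out[f"original_glszm_{k}"] = v
    for k, v in ref_gldm_features(ref_gldm(levels, mask, ng), n_vox).items():
        out[f"original_gldm_{k}"] = v
    n, p, s = ref_ngtdm(levels, mask, ng)
    for k, v in ref_ngtdm_features(n, p, s).items():
        out[f"original_ngtdm_{k}"] = v
    return out


def ref_icc_2_1(m):
    """ICC(2,1) by explicit mean-square arithmetic (definitional loops)."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.sum() / (n * k)
    row_means = [m[i].sum() / k for i in range(n)]
    col_means = [m[:, j].sum() / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def ref_auc(labels, scores):
    """Pair-counting Mann-Whitney AUC."""
    pos = [s for y, s in zip(labels, scores) if y == 1]
    neg = [s for y, s in zip(labels, scores) if y == 0]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
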