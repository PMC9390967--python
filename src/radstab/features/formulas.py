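"""Feature values from intensity samples and texture matrices.

Conventions for degenerate inputs (single grey level, zero variance,
empty denominators) follow the common radiomics defaults and are noted
per feature; a feature is always a finite number, never missing.
Logarithms are base 2 with ``eps = np.spacing(1)`` guarding ``log 0``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "firstorder_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "FIRSTORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "GLDM_NAMES",
    "NGTDM_NAMES",
]

_EPS = np.spacing(1.0)


# ---------------------------------------------------------------- first order

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def firstorder_features(
    values: np.ndarray, voxel_volume: float, bin_width: float = 25.0
) -> dict[str, float]:
    """The 18 first-order statistics of the in-mask intensities.

    ``Entropy`` and ``Uniformity`` use a fixed-bin-width histogram of the
    input values.  ``Kurtosis`` is the raw fourth standardised moment
    (Fisher's 3 is not subtracted); skewness and kurtosis of a constant
    ROI are 0.
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    mean = float(x.mean())
    energy = float(np.sum(x**2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    var = float(np.mean((x - mean) ** 2))
    m2 = var
    if m2 > 0:
        skew = float(np.mean((x - mean) ** 3) / m2**1.5)
        kurt = float(np.mean((x - mean) ** 4) / m2**2)
    else:
        skew, kurt = 0.0, 0.0
    nbins = max(1, int(np.floor((x.max() - x.min()) / bin_width)) + 1)
    counts = np.bincount(
        np.floor((x - x.min()) / bin_width).astype(int), minlength=nbins
    )
    p = counts / n
    p = p[p > 0]
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation": float(
            np.mean(np.abs(robust - robust.mean())) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p**2)),
    }


# --------------------------------------------------------------------- GLCM

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "JointEnergy",
    "JointEntropy",
    "Imc1",
    "Imc2",
    "Idm",
    "Idmn",
    "Id",
    "Idn",
    "InverseVariance",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
    "MCC",
)


def glcm_features(P: np.ndarray) -> dict[str, float]:
    """The 24 co-occurrence features on a symmetric normalised matrix.

    Degenerate cases: ``Correlation`` and ``MCC`` are 1 for a flat region
    (sigma = 0 / Ng = 1); ``Imc1`` is 0 when ``max(HX, HY) = 0``;
    ``Imc2`` is clipped at 0.
    """
    P = np.asarray(P, dtype=np.float64)
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu_x = float(np.sum(i * px))
    sig_x = float(np.sqrt(np.sum((i - mu_x) ** 2 * px)))
    # diagonal (|i-j| = k) and anti-diagonal (i+j = k) marginals
    k_diff = np.arange(ng)
    p_diff = np.array([P[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([P[(ii + jj) == k].sum() for k in k_sum])
    hx = float(-np.sum(px[px > 0] * np.log2(px[px > 0])))
    hxy = float(-np.sum(P[P > 0] * np.log2(P[P > 0])))
    pxpy = np.outer(px, px)
    hxy1 = float(-np.sum(P * np.log2(pxpy + _EPS)))
    hxy2 = float(-np.sum(pxpy[pxpy > 0] * np.log2(pxpy[pxpy > 0])))
    da = float(np.sum(k_diff * p_diff))
    if sig_x > 0:
        corr = float((np.sum(ii * jj * P) - mu_x * mu_x) / sig_x**2)
    else:
        corr = 1.0
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = ii != jj
    inv_var = float(np.sum(P[off] / (ii[off] - jj[off]) ** 2))
    return {
        "Autocorrelation": float(np.sum(ii * jj * P)),
        "JointAverage": mu_x,
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu_x) ** 4 * P)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu_x) ** 3 * P)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu_x) ** 2 * P)),
        "Contrast": float(np.sum((ii - jj) ** 2 * P)),
        "Correlation": corr,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -np.sum(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0]))
        ),
        "DifferenceVariance": float(np.sum((k_diff - da) ** 2 * p_diff)),
        "JointEnergy": float(np.sum(P**2)),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float(np.sum(P / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(P / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(P / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(P / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(P.max()),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "SumEntropy": float(-np.sum(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0]))),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * P)),
        "MCC": _mcc(P, px),
    }


def _mcc(P: np.ndarray, px: np.ndarray) -> float:
    nz = px > 0
    if nz.sum() < 2:
        return 1.0
    Pn = P[np.ix_(nz, nz)]
    pxn = px[nz]
    # Q(i, j) = sum_k P(i,k) P(j,k) / (px(i) py(k)); symmetric marginals.
    Q = (Pn / pxn[:, None]) @ (Pn / pxn[None, :]).T
    eig = np.sort(np.linalg.eigvals(Q).real)
    second = eig[-2]
    return float(np.sqrt(max(0.0, second)))


# ----------------------------------------------------- run-length style bases


def _run_style(P: np.ndarray, n_voxels: float) -> dict[str, float]:
    """Shared arithmetic for GLRLM/GLSZM-style matrices P(level, size)."""
    ng, ns = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    j = np.arange(1, ns + 1, dtype=np.float64)
    nz = float(P.sum())
    pr = P / nz
    pg = P.sum(axis=1)  # per grey level
    ps = P.sum(axis=0)  # per size
    mu_i = float(np.sum(pr.sum(axis=1) * i))
    mu_j = float(np.sum(pr.sum(axis=0) * j))
    pr_pos = pr[pr > 0]
    return {
        "small": float(np.sum(ps / j**2) / nz),
        "large": float(np.sum(ps * j**2) / nz),
        "gln": float(np.sum(pg**2) / nz),
        "glnn": float(np.sum(pg**2) / nz**2),
        "sn": float(np.sum(ps**2) / nz),
        "snn": float(np.sum(ps**2) / nz**2),
        "pct": float(nz / n_voxels),
        "glv": float(np.sum(pr * (i[:, None] - mu_i) ** 2)),
        "sv": float(np.sum(pr * (j[None, :] - mu_j) ** 2)),
        "entropy": float(-np.sum(pr_pos * np.log2(pr_pos))),
        "lgl": float(np.sum(pg / i**2) / nz),
        "hgl": float(np.sum(pg * i**2) / nz),
        "slgl": float(np.sum(P / (i[:, None] ** 2 * j[None, :] ** 2)) / nz),
        "shgl": float(np.sum(P * i[:, None] ** 2 / j[None, :] ** 2) / nz),
        "llgl": float(np.sum(P * j[None, :] ** 2 / i[:, None] ** 2) / nz),
        "lhgl": float(np.sum(P * i[:, None] ** 2 * j[None, :] ** 2) / nz),
    }


GLRLM_NAMES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "GrayLevelVariance",
    "RunVariance",
    "RunEntropy",
    "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis",
    "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)


def glrlm_features(P: np.ndarray, n_voxels: float) -> dict[str, float]:
    """The 16 run-length features on a direction-averaged GLRLM."""
    b = _run_style(P, n_voxels)
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


GLSZM_NAMES = (
    "SmallAreaEmphasis",
    "LargeAreaEmphasis",
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "ZonePercentage",
    "GrayLevelVariance",
    "ZoneVariance",
    "ZoneEntropy",
    "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)


def glszm_features(P: np.ndarray, n_voxels: float) -> dict[str, float]:
    """The 16 size-zone features."""
    b = _run_style(P, n_voxels)
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


GLDM_NAMES = (
    "SmallDependenceEmphasis",
    "LargeDependenceEmphasis",
    "GrayLevelNonUniformity",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "GrayLevelVariance",
    "DependenceVariance",
    "DependenceEntropy",
    "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
)


def gldm_features(P: np.ndarray, n_voxels: float) -> dict[str, float]:
    """The 14 dependence features; note there is no normalised GLN here."""
    b = _run_style(P, n_voxels)
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


# -------------------------------------------------------------------- NGTDM

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def ngtdm_features(
    n: np.ndarray, p: np.ndarray, s: np.ndarray
) -> dict[str, float]:
    """The 5 neighbourhood grey-tone difference features.

    Degenerate conventions: Coarseness is capped at 1e6 when its
    denominator vanishes; Contrast is 0 for a single occupied level;
    Busyness and Strength are 0 when their denominators vanish.
    """
    i = np.arange(1, len(n) + 1, dtype=np.float64)
    nv = float(n.sum())
    occ = p > 0
    ngp = int(occ.sum())
    sum_ps = float(np.sum(p * s))
    coarseness = 1.0 / sum_ps if sum_ps > 0 else 1e6
    if ngp > 1:
        pi, pj = np.meshgrid(p[occ], p[occ], indexing="ij")
        di = i[occ][:, None] - i[occ][None, :]
        contrast = float(
            np.sum(pi * pj * di**2) / (ngp * (ngp - 1)) * (np.sum(s) / nv)
        )
        ipi = i[occ] * p[occ]
        busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
        busyness = sum_ps / busy_den if busy_den > 0 else 0.0
        complexity = float(
            np.sum(
                np.abs(di)
                * (
                    (pi * s[occ][:, None] + pj * s[occ][None, :])
                    / (pi + pj)
                )
            )
            / nv
        )
        strength_num = float(np.sum((pi + pj) * di**2))
        sum_s = float(np.sum(s))
        strength = strength_num / sum_s if sum_s > 0 else 0.0
    else:
        contrast, busyness, complexity, strength = 0.0, 0.0, 0.0, 0.0
    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }
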