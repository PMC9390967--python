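"""Feature-stability scoring with ICC(2,1) and the robustness filter.

A feature is robust when its two-way random-effects, absolute-agreement,
single-measurement intraclass correlation exceeds the threshold
(strictly) for *every* tested perturbation family.  Zero-MAD columns are
nonpredictive and dropped; surviving features are standardised with
train-derived statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ICCReport",
    "RobustFilterConfig",
    "icc_2_1",
    "family_icc",
    "filter_robust",
    "remove_zero_mad",
    "standardize",
]


@dataclass(frozen=True)
class ICCReport:
    feature: str
    family: str  # perturbation family or "test_retest"
    icc: float
    n_subjects: int
    k_versions: int


@dataclass
class RobustFilterConfig:
    icc_threshold: float = 0.75
    require_all_families: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.icc_threshold <= 1.0:
            raise ValueError("icc_threshold must lie in [0, 1]")


def icc_2_1(measurements: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``measurements`` is an ``n_subjects x k_versions`` matrix.  From the
    two-way ANOVA mean squares (rows MS_R, columns MS_C, error MS_E)::

        ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

    The value is <= 1 and may be negative.  A matrix with zero total
    variance has no agreement structure and raises.
    """
    m = np.asarray(measurements, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("measurements must be 2-D (subjects x versions)")
    n, k = m.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if k < 2:
        raise ValueError(f"need at least 2 versions, got {k}")
    if not np.isfinite(m).all():
        raise ValueError("measurements contain non-finite values")
    grand = m.mean()
    if np.allclose(m, grand):
        raise ValueError("degenerate measurement matrix (zero total variance)")
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise ValueError("degenerate measurement matrix (zero denominator)")
    return float((ms_r - ms_e) / denom)


def family_icc(
    baseline_table: pd.DataFrame,
    perturbed_tables: Sequence[pd.DataFrame],
    family: str,
) -> list[ICCReport]:
    """Per-feature ICC(2,1) of [baseline | perturbed versions] matrices.

    All tables must share the same subjects (rows) and features
    (columns); the measurement matrix of a feature stacks its column
    from the baseline table and from every perturbed table.
    """
    tables = [baseline_table, *perturbed_tables]
    base_index = baseline_table.index
    for t in tables[1:]:
        if not t.index.equals(base_index):
            missing = base_index.symmetric_difference(t.index).tolist()
            raise ValueError(f"subject mismatch across tables: {missing}")
        if not t.columns.equals(baseline_table.columns):
            raise ValueError("feature columns differ across tables")
    stack = np.stack([t.to_numpy(dtype=np.float64) for t in tables], axis=2)
    n, k = len(base_index), len(tables)
    reports = []
    for j, feature in enumerate(baseline_table.columns):
        reports.append(
            ICCReport(
                feature=str(feature),
                family=family,
                icc=icc_2_1(stack[:, j, :]),
                n_subjects=n,
                k_versions=k,
            )
        )
    return reports


def filter_robust(
    reports: Iterable[ICCReport], config: RobustFilterConfig | None = None
) -> list[str]:
    """Features whose minimum ICC over families strictly exceeds the cutoff.

    With ``require_all_families=False`` the mean over families is gated
    instead of the minimum.  The result is sorted by feature name, so it
    is independent of report order.
    """
    config = config or RobustFilterConfig()
    by_feature: dict[str, list[float]] = {}
    for r in reports:
        by_feature.setdefault(r.feature, []).append(r.icc)
    agg = min if config.require_all_families else lambda v: sum(v) / len(v)
    return sorted(f for f, iccs in by_feature.items() if agg(iccs) > config.icc_threshold)


def remove_zero_mad(table: pd.DataFrame) -> pd.DataFrame:
    """Drop every column whose median absolute deviation about the median is 0."""
    if table.shape[1] == 0:
        raise ValueError("table has no columns")
    med = table.median(axis=0)
    mad = (table - med).abs().median(axis=0)
    keep = mad > 0
    if not keep.any():
        raise ValueError("all columns have zero MAD")
    return table.loc[:, keep]


def standardize(
    train_table: pd.DataFrame, apply_tables: Sequence[pd.DataFrame] = ()
) -> tuple[pd.DataFrame, ...]:
    """Centre/scale with train-column mean and population SD.

    The identical train-derived affine transform is applied to every
    held-out table, which therefore need not end up zero-mean.
    """
    mean = train_table.mean(axis=0)
    sd = train_table.std(axis=0, ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero train SD for columns: {zero}")
    out = [(train_table - mean) / sd]
    for t in apply_tables:
        out.append((t - mean) / sd)
    return tuple(out)
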