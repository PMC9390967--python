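"""Thirteen feature-scoring/selection methods and the RFA wrapper.

Six filter scorers (CHSQ, RELF, MIM, FSCR, GINI, TSCR) rank features
marginally; eight greedy information-theoretic criteria (MIM, MIFS,
MRMR, JMI, CMIM, CIFE, ICAP, DISR) build a feature set sequentially from
plug-in mutual-information estimates on equal-frequency-discretised
features.  Ties always break by feature-name order so selections are
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SelectorConfig",
    "SCORING_METHODS",
    "GREEDY_METHODS",
    "ALL_METHODS",
    "discretize_equal_frequency",
    "mutual_information",
    "conditional_mutual_information",
    "joint_entropy",
    "score_features",
    "greedy_select",
    "select_features",
    "recursive_feature_addition",
]

SCORING_METHODS = ("CHSQ", "RELF", "MIM", "FSCR", "GINI", "TSCR")
GREEDY_METHODS = ("MIM", "MIFS", "MRMR", "JMI", "CMIM", "CIFE", "ICAP", "DISR")
# MIM belongs to both groups; the union has the 13 study methods.
ALL_METHODS = ("CHSQ", "RELF", "MIM", "FSCR", "MIFS", "GINI", "ICAP", "JMI",
               "CIFE", "CMIM", "DISR", "MRMR", "TSCR")


@dataclass
class SelectorConfig:
    method: str = "MRMR"
    n_select: int = 10
    mi_bins: int = 5
    mifs_beta: float = 1.0
    relieff_k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown selector {self.method!r}")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.mi_bins < 2:
            raise ValueError("mi_bins must be >= 2")


# ------------------------------------------------------------- MI primitives


def discretize_equal_frequency(x: np.ndarray, bins: int = 5) -> np.ndarray:
    """Rank-based equal-frequency binning into integer codes 0..bins-1."""
    order = stats.rankdata(x, method="average")
    return np.minimum((order - 1) * bins // len(x), bins - 1).astype(np.int64)


def _joint_counts(*cols: np.ndarray) -> np.ndarray:
    codes = [np.unique(c, return_inverse=True)[1] for c in cols]
    dims = [c.max() + 1 for c in codes]
    flat = np.zeros(len(cols[0]), dtype=np.int64)
    for c, d in zip(codes, dims):
        flat = flat * d + c
    return np.bincount(flat, minlength=int(np.prod(dims))).reshape(dims)


def _entropy(counts: np.ndarray) -> float:
    p = counts.reshape(-1) / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def joint_entropy(*cols: np.ndarray) -> float:
    """Plug-in joint entropy H(X1, ..., Xm), natural log."""
    return _entropy(_joint_counts(*cols))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in I(X;Y) = H(X) + H(Y) - H(X,Y) >= 0 (natural log)."""
    if len(x) != len(y):
        raise ValueError(f"length mismatch: {len(x)} vs {len(y)}")
    mi = joint_entropy(x) + joint_entropy(y) - joint_entropy(x, y)
    return max(0.0, mi)


def conditional_mutual_information(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> float:
    """Plug-in I(X;Y|Z) = H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)."""
    cmi = (
        joint_entropy(x, z)
        + joint_entropy(y, z)
        - joint_entropy(x, y, z)
        - joint_entropy(z)
    )
    return max(0.0, cmi)


# ------------------------------------------------------------ filter scorers


def _fisher_score(x: np.ndarray, y: np.ndarray) -> float:
    num = den = 0.0
    mu = x.mean()
    for c in np.unique(y):
        xc = x[y == c]
        num += xc.size * (xc.mean() - mu) ** 2
        den += xc.size * xc.var()
    return num / den if den > 0 else np.inf if num > 0 else 0.0


def _welch_t(x: np.ndarray, y: np.ndarray) -> float:
    g0, g1 = x[y == 0], x[y == 1]
    se = np.sqrt(g0.var(ddof=1) / g0.size + g1.var(ddof=1) / g1.size)
    if se == 0:
        return np.inf if g0.mean() != g1.mean() else 0.0
    return abs(g1.mean() - g0.mean()) / se


def _chi_square(x_binned: np.ndarray, y: np.ndarray) -> float:
    table = _joint_counts(x_binned, y)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0
    return float(stats.chi2_contingency(table, correction=False).statistic)


def _gini_gain(x: np.ndarray, y: np.ndarray) -> float:
    """Impurity decrease of the best single threshold split."""

    def gini(labels: np.ndarray) -> float:
        if labels.size == 0:
            return 0.0
        p = np.bincount(labels) / labels.size
        return 1.0 - np.sum(p**2)

    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(y)
    parent = gini(y)
    best = 0.0
    for t in range(1, n):
        if xs[t] == xs[t - 1]:
            continue
        left, right = ys[:t], ys[t:]
        child = (t * gini(left) + (n - t) * gini(right)) / n
        best = max(best, parent - child)
    return best


def _relieff(
    X: np.ndarray, y: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """ReliefF weights using every sample, k nearest hits and misses.

    Features are range-normalised internally (the classic formulation);
    distances are L1.  ``rng`` only breaks exact distance ties.
    """
    n, d = X.shape
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Xn = (X - X.min(axis=0)) / span
    w = np.zeros(d)
    priors = {c: np.mean(y == c) for c in np.unique(y)}
    for i in range(n):
        dist = np.abs(Xn - Xn[i]).sum(axis=1)
        dist[i] = np.inf
        # jitter only to break exact ties deterministically given the seed
        dist = dist + rng.uniform(0, 1e-12, size=n)
        for c in np.unique(y):
            idx = np.nonzero((y == c) & (np.arange(n) != i))[0]
            if idx.size == 0:
                continue
            nearest = idx[np.argsort(dist[idx], kind="stable")[:k]]
            diff = np.abs(Xn[nearest] - Xn[i]).mean(axis=0)
            if c == y[i]:
                w -= diff
            else:
                w += priors[c] / (1.0 - priors[y[i]]) * diff
    return w / n


def score_features(
    table: pd.DataFrame, labels: np.ndarray, method: str,
    config: SelectorConfig | None = None,
) -> pd.Series:
    """One finite relevance score per feature; larger = more relevant."""
    config = config or SelectorConfig(method=method)
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    if min(np.bincount(y)) < 2:
        raise ValueError("need at least 2 samples per class")
    X = table.to_numpy(dtype=np.float64)
    if method == "RELF":
        rng = np.random.default_rng(config.seed)
        scores = _relieff(X, y, config.relieff_k, rng)
    else:
        scorer = {
            "CHSQ": lambda x: _chi_square(
                discretize_equal_frequency(x, config.mi_bins), y
            ),
            "MIM": lambda x: mutual_information(
                discretize_equal_frequency(x, config.mi_bins), y
            ),
            "FSCR": lambda x: _fisher_score(x, y),
            "GINI": lambda x: _gini_gain(x, y),
            "TSCR": lambda x: _welch_t(x, y),
        }.get(method)
        if scorer is None:
            raise ValueError(f"{method!r} is not a scoring method")
        scores = np.array([scorer(X[:, j]) for j in range(X.shape[1])])
    return pd.Series(scores, index=table.columns, name=method)


# ----------------------------------------------------------- greedy criteria


class _MICache:
    """Memoised MI quantities over the discretised feature codes."""

    def __init__(self, codes: np.ndarray, y: np.ndarray):
        self.codes = codes
        self.y = y
        self._rel = {}
        self._red = {}
        self._cred = {}
        self._jmi = {}
        self._disr = {}
        self._cmi_y = {}

    def relevance(self, a: int) -> float:  # I(Xa; Y)
        if a not in self._rel:
            self._rel[a] = mutual_information(self.codes[:, a], self.y)
        return self._rel[a]

    def redundancy(self, a: int, b: int) -> float:  # I(Xa; Xb)
        key = (a, b) if a < b else (b, a)
        if key not in self._red:
            self._red[key] = mutual_information(self.codes[:, a], self.codes[:, b])
        return self._red[key]

    def class_redundancy(self, a: int, b: int) -> float:  # I(Xa; Xb | Y)
        key = (a, b) if a < b else (b, a)
        if key not in self._cred:
            self._cred[key] = conditional_mutual_information(
                self.codes[:, a], self.codes[:, b], self.y
            )
        return self._cred[key]

    def joint_relevance(self, a: int, b: int) -> float:  # I(Xa, Xb; Y)
        key = (a, b) if a < b else (b, a)
        if key not in self._jmi:
            xa, xb = self.codes[:, key[0]], self.codes[:, key[1]]
            self._jmi[key] = (
                joint_entropy(xa, xb)
                + joint_entropy(self.y)
                - joint_entropy(xa, xb, self.y)
            )
        return self._jmi[key]

    def disr_term(self, a: int, b: int) -> float:  # I(Xa,Xb;Y)/H(Xa,Xb,Y)
        key = (a, b) if a < b else (b, a)
        if key not in self._disr:
            xa, xb = self.codes[:, key[0]], self.codes[:, key[1]]
            h = joint_entropy(xa, xb, self.y)
            self._disr[key] = self.joint_relevance(a, b) / h if h > 0 else 0.0
        return self._disr[key]

    def cmi_given(self, a: int, b: int) -> float:  # I(Xa; Y | Xb)
        key = (a, b)
        if key not in self._cmi_y:
            self._cmi_y[key] = conditional_mutual_information(
                self.codes[:, a], self.y, self.codes[:, b]
            )
        return self._cmi_y[key]


def _greedy_criterion(
    method: str, cache: _MICache, cand: int, selected: list[int], beta: float
) -> float:
    rel = cache.relevance(cand)
    if not selected:
        return rel
    if method == "MIM":
        return rel
    if method == "MIFS":
        return rel - beta * sum(cache.redundancy(cand, s) for s in selected)
    if method == "MRMR":
        return rel - sum(cache.redundancy(cand, s) for s in selected) / len(selected)
    if method == "JMI":
        return sum(cache.joint_relevance(cand, s) for s in selected)
    if method == "CMIM":
        return min(cache.cmi_given(cand, s) for s in selected)
    if method == "CIFE":
        return rel - sum(
            cache.redundancy(cand, s) - cache.class_redundancy(cand, s)
            for s in selected
        )
    if method == "ICAP":
        return rel - sum(
            max(0.0, cache.redundancy(cand, s) - cache.class_redundancy(cand, s))
            for s in selected
        )
    if method == "DISR":
        return sum(cache.disr_term(cand, s) for s in selected)
    raise ValueError(f"{method!r} is not a greedy method")


def greedy_select(
    table: pd.DataFrame,
    labels: np.ndarray,
    method: str,
    n_select: int,
    config: SelectorConfig | None = None,
) -> list[str]:
    """Sequential forward selection under one of the 8 MI criteria.

    The first pick is always ``argmax I(X;Y)``; later picks maximise the
    method's criterion given the selected set.  Ties break by
    feature-name order.  ``n_select`` beyond the feature count selects
    everything with a warning.
    """
    if method not in GREEDY_METHODS:
        raise ValueError(f"{method!r} is not a greedy method")
    config = config or SelectorConfig(method=method)
    y = np.asarray(labels, dtype=np.int64)
    X = table.to_numpy(dtype=np.float64)
    n_features = X.shape[1]
    if n_select > n_features:
        warnings.warn(
            f"n_select={n_select} > {n_features} features; selecting all",
            stacklevel=2,
        )
        n_select = n_features
    codes = np.column_stack(
        [discretize_equal_frequency(X[:, j], config.mi_bins) for j in range(n_features)]
    )
    cache = _MICache(codes, y)
    # Stable name order for tie-breaking: iterate candidates in name order.
    name_order = np.argsort(np.asarray(table.columns, dtype=str), kind="stable")
    selected: list[int] = []
    remaining = list(name_order)
    while len(selected) < n_select:
        best, best_score = None, -np.inf
        for cand in remaining:
            score = _greedy_criterion(method, cache, cand, selected, config.mifs_beta)
            if score > best_score:
                best, best_score = cand, score
        selected.append(best)
        remaining.remove(best)
    return [str(table.columns[j]) for j in selected]


def select_features(
    table: pd.DataFrame,
    labels: np.ndarray,
    method: str,
    n_select: int,
    config: SelectorConfig | None = None,
) -> list[str]:
    """Uniform entry point: greedy methods step, scorers take the top-n."""
    config = config or SelectorConfig(method=method, n_select=n_select)
    if method in GREEDY_METHODS:
        return greedy_select(table, labels, method, n_select, config)
    scores = score_features(table, labels, method, config)
    ranked = scores.sort_values(ascending=False, kind="stable")
    # pandas stable sort keeps column order on ties; re-sort tied blocks by name
    ranked = ranked.iloc[
        np.lexsort((np.asarray(ranked.index, dtype=str), -ranked.to_numpy()))
    ]
    return [str(c) for c in ranked.index[: min(n_select, len(ranked))]]


def recursive_feature_addition(
    ranked_features: list[str],
    table: pd.DataFrame,
    labels: np.ndarray,
    estimator,
    cv=None,
    tol: float = 1e-4,
    max_features: int = 20,
    seed: int = 0,
) -> list[str]:
    """Wrapper selection: walk the ranking, keep a feature iff CV AUC improves.

    A feature stays in the subset only when the mean cross-validated AUC
    rises by more than ``tol``; the first ranked feature is always kept.
    The result is a subsequence of ``ranked_features``.
    """
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    if cv is None:
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed)
    y = np.asarray(labels, dtype=np.int64)

    def cv_auc(cols: list[str]) -> float:
        scores = cross_val_score(
            clone(estimator), table[cols].to_numpy(), y, cv=cv, scoring="roc_auc"
        )
        return float(scores.mean())

    subset = [ranked_features[0]]
    best = cv_auc(subset)
    for feat in ranked_features[1:]:
        if len(subset) >= max_features:
            break
        trial = cv_auc(subset + [feat])
        if trial > best + tol:
            subset.append(feat)
            best = trial
    return subset
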