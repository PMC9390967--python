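"""Extractor x selector x classifier model grid with AUC/RSD selection.

Inside every training fold the pipeline standardises, selects features,
rebalances with SMOTE and fits the classifier; the untouched test fold
is then scored.  Nothing fitted ever sees test-fold rows, which is the
leakage guard the stability analysis depends on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .select import SelectorConfig, select_features

__all__ = [
    "CLASSIFIER_NAMES",
    "make_classifier",
    "GridConfig",
    "GridRow",
    "ConfusionMetrics",
    "smote_oversample",
    "stratified_kfold",
    "auc",
    "rsd",
    "run_grid",
    "select_best",
    "confusion_metrics",
    "pooled_out_of_fold_predictions",
]

CLASSIFIER_NAMES = (
    "LogisticRegression",
    "NearestNeighbors",
    "QDA",
    "LinearSVC",
    "RbfSVC",
    "GradientBoosting",
    "MLP",
    "GaussianProcess",
    "DecisionTree",
    "NaiveBayes",
    "RandomForest",
    "AdaBoost",
)


def make_classifier(name: str, seed: int = 0):
    """Instantiate a registry classifier with library-default settings."""
    registry = {
        "LogisticRegression": lambda: LogisticRegression(max_iter=1000),
        "NearestNeighbors": lambda: KNeighborsClassifier(n_neighbors=5),
        "QDA": lambda: QuadraticDiscriminantAnalysis(reg_param=1e-3),
        "LinearSVC": lambda: SVC(kernel="linear", C=1.0, random_state=seed),
        "RbfSVC": lambda: SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed),
        "GradientBoosting": lambda: GradientBoostingClassifier(
            n_estimators=100, max_depth=3, random_state=seed
        ),
        "MLP": lambda: MLPClassifier(
            hidden_layer_sizes=(100,), max_iter=300, random_state=seed
        ),
        "GaussianProcess": lambda: GaussianProcessClassifier(random_state=seed),
        "DecisionTree": lambda: DecisionTreeClassifier(random_state=seed),
        "NaiveBayes": lambda: GaussianNB(),
        "RandomForest": lambda: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "AdaBoost": lambda: AdaBoostClassifier(n_estimators=50, random_state=seed),
    }
    if name not in registry:
        raise ValueError(f"unknown classifier {name!r}")
    return registry[name]()


@dataclass
class GridConfig:
    n_folds: int = 10
    n_select: int = 10
    seed: int = 0
    smote: bool = True
    smote_k: int = 5
    selector_config: SelectorConfig | None = None


@dataclass
class GridRow:
    """Result of one (extractor, selector, classifier) combination."""

    extractor: str
    selector: str
    classifier: str
    fold_aucs: list[float] = field(default_factory=list)
    mean_auc: float = float("nan")
    sd_auc: float = float("nan")
    rsd: float = float("nan")
    selected_features: list[list[str]] = field(default_factory=list)
    failed: bool = False
    error: str = ""

    @property
    def name(self) -> str:
        return f"{self.extractor}_{self.selector}_{self.classifier}"


@dataclass
class ConfusionMetrics:
    acc: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    degenerate: bool = False


def smote_oversample(
    features: np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by interpolating minority samples (SMOTE).

    Each synthetic point is ``x_i + u (x_nn - x_i)`` with ``u ~ U(0,1)``
    and ``x_nn`` one of the ``k`` nearest minority neighbours of a
    randomly drawn minority sample.  Originals are preserved; an already
    balanced input is returned unchanged.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(y, minlength=2)
    if counts[0] == counts[1]:
        return X, y
    minority = int(np.argmin(counts))
    need = int(abs(counts[0] - counts[1]))
    Xm = X[y == minority]
    if len(Xm) < 2:
        raise ValueError("SMOTE needs at least 2 minority samples")
    rng = np.random.default_rng(seed)
    k = min(k_neighbors, len(Xm) - 1)
    d2 = np.sum((Xm[:, None, :] - Xm[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
    base = rng.integers(0, len(Xm), size=need)
    pick = rng.integers(0, k, size=need)
    u = rng.uniform(0.0, 1.0, size=need)
    neighbours = Xm[nn_idx[base, pick]]
    synthetic = Xm[base] + u[:, None] * (neighbours - Xm[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(need, minority, dtype=np.int64)])
    return X_out, y_out


def stratified_kfold(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified k-fold (train_idx, test_idx) pairs."""
    y = np.asarray(labels, dtype=np.int64)
    if min(np.bincount(y)) < k:
        raise ValueError(
            f"smallest class has {min(np.bincount(y))} members < k={k}; "
            "use a smaller k"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(s, method="average")
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def rsd(fold_aucs: Sequence[float]) -> float:
    """Relative standard deviation of fold AUCs: (sample SD / mean) x 100."""
    a = np.asarray(fold_aucs, dtype=np.float64)
    mean = a.mean()
    if mean <= 0:
        raise ValueError("mean AUC must be > 0")
    sd = a.std(ddof=1) if len(a) > 1 else 0.0
    return float(sd / mean * 100.0)


def _standardize_fold(
    train: pd.DataFrame, others: Sequence[pd.DataFrame] = ()
) -> list[pd.DataFrame]:
    """Train-fitted centre/scale that tolerates constant columns (scale 1).

    Upstream zero-MAD filtering removes globally constant features, but a
    column can still be constant within one training fold; treating its
    scale as 1 keeps the fold usable instead of failing the row.
    """
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0).replace(0.0, 1.0)
    return [(t - mean) / sd for t in (train, *others)]


def _fold_scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "predict_proba"):
        return clf.predict_proba(X)[:, 1]
    return clf.decision_function(X)


def _evaluate_fold(
    table: pd.DataFrame,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    features: list[str],
    classifier_name: str,
    config: GridConfig,
) -> float:
    train = table.iloc[train_idx][features]
    test = table.iloc[test_idx][features]
    train_z, test_z = _standardize_fold(train, [test])
    X_tr, y_tr = train_z.to_numpy(), y[train_idx]
    if config.smote:
        X_tr, y_tr = smote_oversample(X_tr, y_tr, config.smote_k, seed=config.seed)
    clf = make_classifier(classifier_name, seed=config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(X_tr, y_tr)
        scores = _fold_scores(clf, test_z.to_numpy())
    return auc(y[test_idx], scores)


def run_grid(
    feature_tables: Mapping[str, pd.DataFrame],
    labels: np.ndarray,
    selectors: Sequence[str],
    classifiers: Sequence[str],
    config: GridConfig | None = None,
) -> list[GridRow]:
    """Evaluate every (extractor, selector, classifier) combination.

    Feature selection runs once per (extractor, fold, selector) on the
    standardised training rows and is shared across classifiers.  A
    failing fold marks the whole row failed (with diagnostics) without
    stopping the run.
    """
    config = config or GridConfig()
    y = np.asarray(labels, dtype=np.int64)
    folds = stratified_kfold(y, config.n_folds, config.seed)
    rows: list[GridRow] = []
    for extractor, table in feature_tables.items():
        if len(table) != len(y):
            raise ValueError(f"table {extractor!r} is not row-aligned with labels")
        # feature choice per (fold, selector), shared by all classifiers
        fold_features: dict[tuple[int, str], list[str] | Exception] = {}
        for f, (tr, _) in enumerate(folds):
            train = table.iloc[tr]
            train_z = _standardize_fold(train)[0]
            sel_cfg = config.selector_config or SelectorConfig(
                n_select=config.n_select, seed=config.seed
            )
            for selector in selectors:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fold_features[(f, selector)] = select_features(
                            train_z, y[tr], selector, config.n_select, sel_cfg
                        )
                except Exception as exc:  # noqa: BLE001 - diagnostics per row
                    fold_features[(f, selector)] = exc
        for selector in selectors:
            for classifier in classifiers:
                row = GridRow(extractor, selector, classifier)
                try:
                    for f, (tr, te) in enumerate(folds):
                        feats = fold_features[(f, selector)]
                        if isinstance(feats, Exception):
                            raise feats
                        row.selected_features.append(feats)
                        row.fold_aucs.append(
                            _evaluate_fold(table, y, tr, te, feats, classifier, config)
                        )
                    row.mean_auc = float(np.mean(row.fold_aucs))
                    row.sd_auc = (
                        float(np.std(row.fold_aucs, ddof=1))
                        if len(row.fold_aucs) > 1
                        else 0.0
                    )
                    row.rsd = rsd(row.fold_aucs)
                except Exception as exc:  # noqa: BLE001
                    row.failed = True
                    row.error = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return rows


def select_best(rows: Sequence[GridRow]) -> GridRow:
    """Highest mean AUC; ties break by lowest RSD, then by name order."""
    ok = [r for r in rows if not r.failed]
    if not ok:
        raise ValueError("all grid rows failed")
    return min(ok, key=lambda r: (-r.mean_auc, r.rsd, r.name))


def confusion_metrics(labels: np.ndarray, predictions: np.ndarray) -> ConfusionMetrics:
    """ACC / sensitivity / specificity / precision / F1 from binary predictions.

    Empty denominators yield 0 with ``degenerate=True``.
    """
    y = np.asarray(labels, dtype=np.int64)
    p = np.asarray(predictions, dtype=np.int64)
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    degenerate = False

    def ratio(num: int, den: int) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) > 0 else 0.0
    return ConfusionMetrics(
        acc=(tp + tn) / len(y),
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
        degenerate=degenerate,
    )


def pooled_out_of_fold_predictions(
    table: pd.DataFrame,
    labels: np.ndarray,
    selector: str,
    classifier: str,
    config: GridConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled out-of-fold hard predictions and scores for one combination."""
    config = config or GridConfig()
    y = np.asarray(labels, dtype=np.int64)
    folds = stratified_kfold(y, config.n_folds, config.seed)
    preds = np.zeros(len(y), dtype=np.int64)
    scores = np.zeros(len(y))
    for tr, te in folds:
        train_z = _standardize_fold(table.iloc[tr])[0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            feats = select_features(
                train_z, y[tr], selector, config.n_select,
                config.selector_config
                or SelectorConfig(n_select=config.n_select, seed=config.seed),
            )
            tr_z, te_z = _standardize_fold(table.iloc[tr][feats], [table.iloc[te][feats]])
            X_tr, y_tr = tr_z.to_numpy(), y[tr]
            if config.smote:
                X_tr, y_tr = smote_oversample(X_tr, y_tr, config.smote_k, config.seed)
            clf = make_classifier(classifier, seed=config.seed)
            clf.fit(X_tr, y_tr)
            preds[te] = clf.predict(te_z.to_numpy())
            scores[te] = _fold_scores(clf, te_z.to_numpy())
    return preds, scores
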