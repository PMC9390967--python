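import numpy as np
import pandas as pd
import pytest

from radstab.grid import (
    CLASSIFIER_NAMES,
    ConfusionMetrics,
    GridConfig,
    GridRow,
    auc,
    confusion_metrics,
    make_classifier,
    rsd,
    run_grid,
    select_best,
    smote_oversample,
    stratified_kfold,
)

import _oracles


def toy_tables(rng, n=40, n_features=8, effect=2.0):
    y = np.array([1] * (n * 3 // 4) + [0] * (n - n * 3 // 4))
    data = rng.normal(size=(n, n_features))
    data[:, 0] += y * effect
    data[:, 1] -= y * effect * 0.5
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    cols = [f"f{j}" for j in range(n_features)]
    return {"ext": pd.DataFrame(data, index=idx, columns=cols)}, y


class TestSMOTE:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.repeat([0, 1], 5)
        X2, y2 = smote_oversample(X, y)
        assert X2 is X and y2 is y

    def test_convexity_1d(self):
        # [TRIVIAL] minority {0, 1}: synthetic points stay inside [0, 1].
        X = np.array([[0.0], [1.0]] + [[5.0]] * 10)
        y = np.array([1, 1] + [0] * 10)
        X2, y2 = smote_oversample(X, y, seed=3)
        synth = X2[len(X):]
        assert np.all((synth >= 0.0) & (synth <= 1.0))

    def test_counts_balanced_across_imbalances(self, rng):
        # [DERIVED] class counts equal for random imbalances and seeds.
        for seed in range(5):
            r = np.random.default_rng(seed)
            n_min = int(r.integers(2, 10))
            n_maj = int(r.integers(n_min, 40))
            X = r.normal(size=(n_min + n_maj, 4))
            y = np.array([1] * n_min + [0] * n_maj)
            _, y2 = smote_oversample(X, y, seed=seed)
            assert np.bincount(y2)[0] == np.bincount(y2)[1]

    def test_originals_preserved(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array([1] * 3 + [0] * 9)
        X2, _ = smote_oversample(X, y, seed=0)
        assert np.array_equal(X2[:12], X)

    def test_tiny_minority_errors(self, rng):
        X = rng.normal(size=(5, 2))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="minority"):
            smote_oversample(X, y)


class TestStratifiedKFold:
    def test_cohort_proportions(self):
        # [DERIVED] 124/33 at k=10: folds hold 12-13 positives, 3-4 negatives.
        y = np.array([1] * 124 + [0] * 33)
        folds = stratified_kfold(y, 10, seed=0)
        for _, te in folds:
            assert 12 <= (y[te] == 1).sum() <= 13
            assert 3 <= (y[te] == 0).sum() <= 4

    def test_partition_exact(self, rng):
        y = rng.integers(0, 2, size=50)
        y[:10] = 1
        y[10:20] = 0
        folds = stratified_kfold(y, 5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(50))

    def test_same_seed_identical(self):
        y = np.array([1] * 20 + [0] * 10)
        a = stratified_kfold(y, 5, seed=7)
        b = stratified_kfold(y, 5, seed=7)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tea, teb)

    def test_small_class_errors(self):
        y = np.array([1] * 20 + [0] * 3)
        with pytest.raises(ValueError, match="smaller k"):
            stratified_kfold(y, 10)


class TestAUC:
    def test_perfect_ranking(self):
        assert auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9])) == 1.0

    def test_random_scores_near_half(self, rng):
        y = rng.integers(0, 2, size=4000)
        s = rng.normal(size=4000)
        assert auc(y, s) == pytest.approx(0.5, abs=0.05)

    def test_tie_pair_counting_oracle(self):
        # [DERIVED] 4-sample toy with one tie.
        y = np.array([1, 1, 0, 0])
        s = np.array([0.9, 0.5, 0.5, 0.1])
        assert auc(y, s) == pytest.approx(_oracles.ref_auc(y, s))
        assert auc(y, s) == pytest.approx((2 + 0.5 + 1) / 4)

    def test_random_vectors_match_pair_counting(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.normal(size=n), 1)  # rounding forces ties
            assert auc(y, s) == pytest.approx(_oracles.ref_auc(y, s), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, size=200)
        y[:5], y[5:10] = 1, 0
        s = rng.normal(size=200)
        assert auc(y, s) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auc(np.ones(4, dtype=int), np.arange(4.0))


class TestRSD:
    def test_identical_folds_zero(self):
        assert rsd([0.8] * 10) == 0.0

    def test_two_point_arithmetic(self):
        # [DERIVED] sd({0.8, 1.0}) = 0.2/sqrt(2); RSD = 100 * sd / 0.9.
        expected = 100.0 * (0.2 / np.sqrt(2)) / 0.9
        assert rsd([0.8, 1.0]) == pytest.approx(expected, abs=1e-12)

    def test_scale_invariance(self, rng):
        folds = rng.uniform(0.6, 1.0, size=10)
        assert rsd(folds * 0.5) == pytest.approx(rsd(folds), abs=1e-10)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            rsd([0.0, 0.0])


class TestRunGrid:
    def test_single_combination(self, rng):
        tables, y = toy_tables(rng)
        rows = run_grid(tables, y, ["MIM"], ["NaiveBayes"],
                        GridConfig(n_folds=3, n_select=2))
        assert len(rows) == 1
        row = rows[0]
        assert not row.failed
        assert len(row.fold_aucs) == 3
        assert row.rsd == pytest.approx(
            100 * np.std(row.fold_aucs, ddof=1) / np.mean(row.fold_aucs), abs=1e-10
        )
        assert row.name == "ext_MIM_NaiveBayes"

    def test_strong_signal_high_auc(self, rng):
        tables, y = toy_tables(rng, effect=3.0)
        rows = run_grid(tables, y, ["FSCR"], ["LogisticRegression"],
                        GridConfig(n_folds=3, n_select=2))
        assert rows[0].mean_auc > 0.9

    def test_cartesian_row_count(self, rng):
        tables, y = toy_tables(rng)
        tables["ext2"] = tables["ext"] * 2.0
        rows = run_grid(tables, y, ["MIM", "TSCR"], ["NaiveBayes", "DecisionTree"],
                        GridConfig(n_folds=3, n_select=2))
        assert len(rows) == 2 * 2 * 2
        names = {r.name for r in rows}
        assert len(names) == 8

    def test_misaligned_table_raises(self, rng):
        tables, y = toy_tables(rng)
        with pytest.raises(ValueError, match="row-aligned"):
            run_grid(tables, y[:-2], ["MIM"], ["NaiveBayes"],
                     GridConfig(n_folds=3))

    def test_leakage_guard_null_auc(self):
        # [DERIVED] label-permuted data must stay near chance even though
        # selection + SMOTE + standardisation run inside the pipeline.
        aucs = []
        for seed in range(3):
            r = np.random.default_rng(seed)
            tables, y = toy_tables(r, n=60, n_features=20, effect=0.0)
            y_perm = r.permutation(y)
            rows = run_grid(tables, y_perm, ["MIM"], ["LogisticRegression"],
                            GridConfig(n_folds=5, n_select=3, seed=seed))
            aucs.append(rows[0].mean_auc)
        assert 0.35 < np.mean(aucs) < 0.65


class TestSelectBest:
    def _row(self, name, mean_auc, rsd_val):
        r = GridRow("e", name, "c")
        r.mean_auc, r.rsd = mean_auc, rsd_val
        return r

    def test_auc_primary(self):
        rows = [self._row("a", 0.9, 2.0), self._row("b", 0.96, 5.0)]
        assert select_best(rows).mean_auc == 0.96

    def test_rsd_breaks_auc_ties(self):
        # [PAPER] equal AUC rows resolved by the lower RSD.
        rows = [self._row("a", 0.96, 0.61), self._row("b", 0.96, 0.50)]
        assert select_best(rows).rsd == 0.50

    def test_single_row(self):
        rows = [self._row("only", 0.7, 1.0)]
        assert select_best(rows) is rows[0]

    def test_all_failed_errors(self):
        r = self._row("x", 0.9, 1.0)
        r.failed = True
        with pytest.raises(ValueError):
            select_best([r])

    def test_name_breaks_full_ties(self):
        rows = [self._row("b", 0.9, 1.0), self._row("a", 0.9, 1.0)]
        assert select_best(rows).selector == "a"


class TestConfusionMetrics:
    def test_all_correct(self):
        y = np.array([0, 1, 0, 1])
        m = confusion_metrics(y, y)
        assert (m.acc, m.sensitivity, m.specificity, m.precision, m.f1) == (
            1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_hand_confusion_matrix(self):
        # [DERIVED] TP=9 FN=1 FP=2 TN=8.
        y = np.array([1] * 10 + [0] * 10)
        p = np.array([1] * 9 + [0] + [1] * 2 + [0] * 8)
        m = confusion_metrics(y, p)
        assert m.acc == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.precision == pytest.approx(9 / 11)
        assert m.f1 == pytest.approx(2 * (9 / 11) * 0.9 / ((9 / 11) + 0.9))

    def test_swapping_convention_swaps_sens_spec(self, rng):
        y = rng.integers(0, 2, size=30)
        y[:3], y[3:6] = 0, 1
        p = rng.integers(0, 2, size=30)
        m = confusion_metrics(y, p)
        m_swapped = confusion_metrics(1 - y, 1 - p)
        assert m.sensitivity == pytest.approx(m_swapped.specificity)
        assert m.specificity == pytest.approx(m_swapped.sensitivity)

    def test_degenerate_flag(self):
        y = np.array([0, 0, 1, 1])
        p = np.zeros(4, dtype=int)
        m = confusion_metrics(y, p)
        assert m.degenerate and m.precision == 0.0


class TestClassifierRegistry:
    def test_twelve_names(self):
        assert len(CLASSIFIER_NAMES) == 12

    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_fit_and_score(self, name, rng):
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] > 0).astype(int)
        clf = make_classifier(name, seed=0)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        assert hasattr(clf, "predict_proba") or hasattr(clf, "decision_function")

    def test_unknown_name(self):
        with pytest.raises(ValueError):
            make_classifier("nope")
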