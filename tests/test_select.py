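import itertools

import numpy as np
import pandas as pd
import pytest

from radstab.select import (
    ALL_METHODS,
    GREEDY_METHODS,
    SCORING_METHODS,
    SelectorConfig,
    conditional_mutual_information,
    discretize_equal_frequency,
    greedy_select,
    joint_entropy,
    mutual_information,
    recursive_feature_addition,
    score_features,
    select_features,
)


def toy_table(rng, n=60, n_noise=4):
    y = np.repeat([0, 1], n // 2)
    signal = y * 2.0 + rng.normal(scale=0.5, size=n)
    cols = {"signal": signal}
    for j in range(n_noise):
        cols[f"noise{j}"] = rng.normal(size=n)
    return pd.DataFrame(cols), y


class TestMutualInformation:
    def test_independent_near_zero(self, rng):
        x = rng.integers(0, 3, size=20000)
        y = rng.integers(0, 2, size=20000)
        assert mutual_information(x, y) < 0.005

    def test_identity_ln_l(self):
        # [TRIVIAL] y = x with L equiprobable levels -> ln L.
        x = np.repeat(np.arange(4), 25)
        assert mutual_information(x, x) == pytest.approx(np.log(4))

    def test_three_level_joint_oracle(self):
        # [DERIVED] direct sum p log(p/(px py)) on a fixed 3-level table.
        joint = np.array([[0.2, 0.1], [0.05, 0.25], [0.3, 0.1]])
        counts = (joint * 100).astype(int)
        x = np.repeat(np.arange(3), counts.sum(axis=1))
        y = np.concatenate([
            np.repeat([0, 1], counts[i]) for i in range(3)
        ])
        px, py = joint.sum(axis=1), joint.sum(axis=0)
        expected = sum(
            joint[i, j] * np.log(joint[i, j] / (px[i] * py[j]))
            for i in range(3)
            for j in range(2)
        )
        assert mutual_information(x, y) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(20):
            x = rng.integers(0, 4, size=50)
            y = rng.integers(0, 2, size=50)
            assert mutual_information(x, y) >= 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            mutual_information(np.arange(4), np.arange(5))

    def test_chain_identity(self, rng):
        # I(X,Xs;Y) = I(Xs;Y) + I(X;Y|Xs) on toy tables.
        for _ in range(10):
            x = rng.integers(0, 3, size=80)
            xs = rng.integers(0, 3, size=80)
            y = rng.integers(0, 2, size=80)
            lhs = (
                joint_entropy(x, xs)
                + joint_entropy(y)
                - joint_entropy(x, xs, y)
            )
            rhs = mutual_information(xs, y) + conditional_mutual_information(x, y, xs)
            assert lhs == pytest.approx(rhs, abs=1e-10)

    def test_equal_frequency_binning(self, rng):
        x = rng.normal(size=100)
        codes = discretize_equal_frequency(x, 5)
        counts = np.bincount(codes)
        assert len(counts) == 5 and counts.min() == counts.max() == 20


class TestScorers:
    @pytest.mark.parametrize("method", SCORING_METHODS)
    def test_perfect_predictor_ranks_first(self, method, rng):
        table, y = toy_table(rng)
        table["perfect"] = y.astype(float)
        scores = score_features(table, y, method)
        # ties possible (e.g. GINI saturates on any separating feature)
        assert scores["perfect"] == scores.max()
        assert scores["perfect"] > scores[[f"noise{j}" for j in range(4)]].max()

    def test_fisher_score_formula_oracle(self):
        # [DERIVED] class means 0/1, within-class variances 0.25, balanced.
        n = 40
        y = np.repeat([0, 1], n // 2)
        x = np.where(y == 0, 0.0, 1.0) + np.tile([-0.5, 0.5], n // 2)
        table = pd.DataFrame({"x": x})
        var0 = x[y == 0].var()
        mu = x.mean()
        expected = (
            (n // 2) * (x[y == 0].mean() - mu) ** 2
            + (n // 2) * (x[y == 1].mean() - mu) ** 2
        ) / ((n // 2) * var0 + (n // 2) * x[y == 1].var())
        got = score_features(table, y, "FSCR")["x"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_relieff_noise_feature_near_zero(self, rng):
        # [DERIVED] Monte-Carlo: label-independent feature weights ~ 0.
        weights = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            table = pd.DataFrame({
                "signal": y + r.normal(scale=0.3, size=60),
                "noise": r.normal(size=60),
            })
            s = score_features(table, y, "RELF", SelectorConfig(method="RELF", seed=seed))
            weights.append(s["noise"])
            assert s["signal"] > s["noise"]
        assert abs(np.mean(weights)) < 0.05

    def test_welch_t_matches_scipy(self, rng):
        from scipy import stats

        table, y = toy_table(rng)
        got = score_features(table, y, "TSCR")
        for col in table.columns:
            ref = abs(stats.ttest_ind(
                table[col][y == 1], table[col][y == 0], equal_var=False
            ).statistic)
            assert got[col] == pytest.approx(ref, abs=1e-10)

    def test_chsq_matches_scipy_contingency(self, rng):
        from scipy import stats

        table, y = toy_table(rng)
        got = score_features(table, y, "CHSQ", SelectorConfig(method="CHSQ"))
        col = "signal"
        binned = discretize_equal_frequency(table[col].to_numpy(), 5)
        ref = stats.chi2_contingency(
            pd.crosstab(binned, y).to_numpy(), correction=False
        ).statistic
        assert got[col] == pytest.approx(ref, abs=1e-10)

    def test_single_class_errors(self, rng):
        table, _ = toy_table(rng)
        with pytest.raises(ValueError):
            score_features(table, np.zeros(len(table), dtype=int), "MIM")

    def test_permutation_invariance(self, rng):
        table, y = toy_table(rng)
        perm = rng.permutation(len(y))
        for method in ("MIM", "FSCR", "TSCR", "CHSQ", "GINI"):
            a = score_features(table, y, method)
            b = score_features(table.iloc[perm].reset_index(drop=True), y[perm], method)
            assert np.allclose(a.to_numpy(), b.to_numpy())


class TestGreedy:
    def test_first_pick_is_max_relevance(self, rng):
        table, y = toy_table(rng)
        mim_top = greedy_select(table, y, "MIM", 1)[0]
        for method in GREEDY_METHODS:
            assert greedy_select(table, y, method, 1)[0] == mim_top

    def test_duplicate_column_behaviour(self, rng):
        # [DERIVED] redundancy-penalised criteria never pick the duplicate
        # second; MIM always does.
        table, y = toy_table(rng, n_noise=3)
        table["signal_dup"] = table["signal"].to_numpy().copy()
        assert greedy_select(table, y, "MIM", 2) == ["signal", "signal_dup"]
        for method in ("MRMR", "MIFS"):
            second = greedy_select(table, y, method, 2)[1]
            assert second != "signal_dup", method

    def test_greedy_equals_bruteforce_per_step(self, rng):
        # [DERIVED] exhaustive criterion evaluation on 4 features, 2 steps.
        from radstab.select import _MICache, _greedy_criterion

        table, y = toy_table(rng, n_noise=3)
        cfg = SelectorConfig(method="MRMR")
        codes = np.column_stack([
            discretize_equal_frequency(table[c].to_numpy(), cfg.mi_bins)
            for c in table.columns
        ])
        for method in ("MRMR", "JMI", "CMIM"):
            got = greedy_select(table, y, method, 2, cfg)
            cache = _MICache(codes, y)
            names = list(table.columns)
            sel: list[int] = []
            for _ in range(2):
                cands = [j for j in range(len(names)) if j not in sel]
                scored = [
                    (-_greedy_criterion(method, cache, j, sel, 1.0), names[j], j)
                    for j in cands
                ]
                scored.sort()
                sel.append(scored[0][2])
            assert got == [names[j] for j in sel], method

    def test_n_select_exceeds_features_warns(self, rng):
        table, y = toy_table(rng, n_noise=2)
        with pytest.warns(UserWarning, match="selecting all"):
            out = greedy_select(table, y, "MRMR", 50)
        assert sorted(out) == sorted(table.columns)

    def test_selects_requested_count(self, rng):
        table, y = toy_table(rng, n_noise=6)
        for method in GREEDY_METHODS:
            assert len(greedy_select(table, y, method, 3)) == 3

    def test_select_features_uniform_entry(self, rng):
        table, y = toy_table(rng)
        for method in ALL_METHODS:
            out = select_features(table, y, method, 2)
            assert len(out) == 2 and len(set(out)) == 2


class TestRFA:
    def test_recovers_informative_feature(self):
        # [DERIVED] synthetic recovery over 5 seeds.
        from sklearn.linear_model import LogisticRegression

        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            table, y = toy_table(r, n=80, n_noise=6)
            ranked = select_features(table, y, "MIM", len(table.columns))
            subset = recursive_feature_addition(
                ranked, table, y, LogisticRegression(max_iter=500), seed=seed
            )
            hits += "signal" in subset
        assert hits >= 4

    def test_infinite_tol_keeps_only_first(self, rng):
        from sklearn.linear_model import LogisticRegression

        table, y = toy_table(rng)
        ranked = list(table.columns)
        subset = recursive_feature_addition(
            ranked, table, y, LogisticRegression(), tol=np.inf
        )
        assert subset == [ranked[0]]

    def test_output_is_subsequence_of_ranking(self, rng):
        from sklearn.tree import DecisionTreeClassifier

        table, y = toy_table(rng, n_noise=5)
        ranked = list(table.columns)
        subset = recursive_feature_addition(
            ranked, table, y, DecisionTreeClassifier(random_state=0)
        )
        it = iter(ranked)
        assert all(f in it for f in subset)
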