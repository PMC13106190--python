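"""Scenario mapping, LOSO, SMOTE, majority voting, metrics, bootstrap, McNemar."""

import logging

import numpy as np
import pytest
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from bradykin.evaluate import (SCENARIOS, _fast_metric, aggregate_majority,
                               bootstrap_ci, compute_metrics, loso_splits,
                               map_labels, mcnemar_compare, smote_balance)


class TestScenarios:
    def test_raw_four_folds_into_three(self):
        assert map_labels([4], "precise")[0] == 3

    def test_critical_mapping(self):
        assert map_labels([2], "critical")[0] == 0
        assert map_labels([3], "critical")[0] == 1

    def test_abnormal_mapping(self):
        np.testing.assert_array_equal(map_labels([0, 1, 2, 3], "abnormal"),
                                      [0, 1, 1, 1])

    def test_precise_identity(self):
        np.testing.assert_array_equal(map_labels([0, 1, 2, 3], "precise"),
                                      [0, 1, 2, 3])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            map_labels([5], "precise")


class TestLoso:
    def test_one_fold_per_subject(self):
        subj = [f"S{i}" for i in range(29) for _ in range(10)]
        folds = loso_splits(subj)
        assert len(folds) == 29
        tests = [t for _, t in folds]
        assert sorted(tests) == sorted(set(subj))
        for train, test in folds:
            assert test not in train
            assert set(train) | {test} == set(subj)

    def test_single_subject_raises(self):
        with pytest.raises(ValueError):
            loso_splits(["only"] * 5)


class TestSmote:
    def _counts(self, y):
        vals, counts = np.unique(y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def test_exact_quarter_balance(self, rng):
        y = np.repeat([0, 1, 2, 3], [10, 30, 20, 40])
        X = rng.normal(size=(len(y), 5)) + y[:, None]
        Xb, yb = smote_balance(X, y, seed=0)
        assert self._counts(yb) == {0: 40, 1: 40, 2: 40, 3: 40}
        assert len(yb) == 160  # each class exactly 25%

    def test_binary_half_balance(self, rng):
        y = np.repeat([0, 1], [8, 20])
        Xb, yb = smote_balance(rng.normal(size=(28, 3)), y, seed=0)
        assert self._counts(yb) == {0: 20, 1: 20}

    def test_balanced_input_unchanged(self, rng):
        y = np.repeat([0, 1], 10)
        X = rng.normal(size=(20, 4))
        Xb, yb = smote_balance(X, y, seed=0)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_originals_preserved_and_synthetic_in_hull(self, rng):
        y = np.repeat([0, 1], [5, 25])
        X = rng.normal(size=(30, 3)) + 10 * y[:, None]
        Xb, yb = smote_balance(X, y, seed=3)
        np.testing.assert_array_equal(Xb[:30], X)
        new = Xb[30:]
        assert np.all(yb[30:] == 0)  # only the minority class grew
        x0 = X[y == 0]
        assert np.all(new >= x0.min(axis=0) - 1e-12)
        assert np.all(new <= x0.max(axis=0) + 1e-12)

    def test_deterministic_under_seed(self, rng):
        y = np.repeat([0, 1], [4, 12])
        X = rng.normal(size=(16, 2))
        a = smote_balance(X, y, seed=9)
        b = smote_balance(X, y, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_singleton_class_fallback_logged(self, rng, caplog):
        y = np.array([0] + [1] * 6)
        X = rng.normal(size=(7, 2))
        with caplog.at_level(logging.WARNING):
            Xb, yb = smote_balance(X, y, seed=0)
        assert self._counts(yb) == {0: 6, 1: 6}
        assert any("fallback" in r.message for r in caplog.records)
        np.testing.assert_array_equal(Xb[yb == 0], np.tile(X[0], (6, 1)))


class TestMajorityVote:
    def test_strict_majority(self):
        assert aggregate_majority([1, 1, 2]) == 1

    def test_tie_breaks_toward_severe(self):
        assert aggregate_majority([1, 2]) == 2

    def test_unanimous(self):
        assert aggregate_majority([3, 3, 3]) == 3

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_majority([])


def brute_force_auc(y_true, scores):
    """Pairwise-concordance AUC oracle: fraction of positive-negative pairs
    ranked correctly, ties counting one half."""
    pos = [s for t, s in zip(y_true, scores) if t == 1]
    neg = [s for t, s in zip(y_true, scores) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 2, 3, 1])
        prob = np.eye(4)[y]
        m = compute_metrics(y, y, prob, classes=[0, 1, 2, 3])
        assert m["accuracy"] == m["f1"] == m["auc"] == 1.0
        assert m["rmse"] == 0.0

    def test_rmse_hand_value(self):
        m = compute_metrics([0, 3], [1, 1])
        assert m["rmse"] == pytest.approx(np.sqrt(2.5))

    def test_binary_auc_hand_value(self):
        y = [0, 0, 1, 1]
        p1 = np.array([0.1, 0.4, 0.35, 0.8])
        prob = np.stack([1 - p1, p1], axis=1)
        m = compute_metrics(y, [0, 0, 1, 1], prob, classes=[0, 1])
        assert m["auc"] == pytest.approx(0.75)
        assert brute_force_auc(y, p1) == pytest.approx(0.75)

    def test_auc_matches_pairwise_oracle_on_small_inputs(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 21))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            p1 = np.round(rng.uniform(size=n), 2)  # rounding forces some ties
            prob = np.stack([1 - p1, p1], axis=1)
            m = compute_metrics(y, y, prob, classes=[0, 1])
            assert m["auc"] == pytest.approx(brute_force_auc(y, p1), abs=1e-12)

    def test_fast_metrics_agree_with_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            classes = np.arange(4)
            y = rng.integers(0, 4, size=n)
            pred = rng.integers(0, 4, size=n)
            prob = rng.dirichlet(np.ones(4), size=n)
            ref = compute_metrics(y, pred, prob, classes=classes)
            for metric in ("accuracy", "precision", "recall", "f1", "rmse", "auc"):
                fast = _fast_metric(metric, y, pred, prob, classes)
                if np.isnan(ref[metric]):
                    assert np.isnan(fast)
                else:
                    assert fast == pytest.approx(ref[metric], abs=1e-12), metric

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0])


class TestBootstrap:
    def test_constant_correct_predictions_give_degenerate_ci(self):
        y = np.array([0, 0, 1, 1, 1])
        point, lo, hi = bootstrap_ci(y, y, None, "accuracy", B=200, seed=0)
        assert (point, lo, hi) == (1.0, 1.0, 1.0)

    def test_ci_brackets_point(self, rng):
        y = rng.integers(0, 2, size=40)
        pred = np.where(rng.uniform(size=40) < 0.8, y, 1 - y)
        for metric in ("accuracy", "f1", "rmse"):
            point, lo, hi = bootstrap_ci(y, pred, None, metric, B=500, seed=1)
            assert lo - 1e-12 <= point <= hi + 1e-12

    def test_ci_narrows_with_sample_size(self):
        """Percentile CI width shrinks roughly as 1/sqrt(n)."""
        widths = {}
        for n in (100, 400):
            w = []
            for seed in range(20):
                r = np.random.default_rng(seed)
                y = r.integers(0, 2, size=n)
                pred = np.where(r.uniform(size=n) < 0.8, y, 1 - y)
                _, lo, hi = bootstrap_ci(y, pred, None, "accuracy", B=300, seed=seed)
                w.append(hi - lo)
            widths[n] = np.mean(w)
        assert widths[400] < widths[100]


class TestMcNemar:
    def test_identical_predictions(self):
        y = np.arange(10) % 3
        res = mcnemar_compare(y, y, y)
        assert res.b == res.c == 0 and res.p_value == 1.0

    def test_one_sided_discordance_exact_value(self):
        y = np.zeros(10, int)
        a = np.zeros(10, int)          # always right
        b = np.ones(10, int)           # always wrong
        res = mcnemar_compare(y, a, b)
        assert (res.b, res.c) == (10, 0)
        assert res.p_value == pytest.approx(2 * 0.5**10)
        assert res.exact

    def test_symmetric_discordance(self):
        y = np.zeros(10, int)
        a = np.array([0] * 5 + [1] * 5)
        b = np.array([1] * 5 + [0] * 5)
        res = mcnemar_compare(y, a, b)
        assert (res.b, res.c) == (5, 5)
        assert res.p_value == 1.0

    def test_chi_square_branch_matches_statsmodels(self, rng):
        y = np.zeros(60, int)
        a = (rng.uniform(size=60) < 0.4).astype(int)
        b = (rng.uniform(size=60) < 0.4).astype(int)
        res = mcnemar_compare(y, a, b)
        if res.b + res.c >= 25:
            table = np.array([[np.sum((a == y) & (b == y)), res.b],
                              [res.c, np.sum((a != y) & (b != y))]])
            ref = sm_mcnemar(table, exact=False, correction=True)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_bonferroni_threshold(self):
        y = np.zeros(12, int)
        a = np.zeros(12, int)
        b = np.ones(12, int)  # p = 2 * 0.5**12 ~ 4.9e-4
        assert mcnemar_compare(y, a, b, n_comparisons=1).significant
        assert not mcnemar_compare(y, a, b, n_comparisons=200).significant
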