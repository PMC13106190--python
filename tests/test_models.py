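"""Feature ranking, greedy selection, tuning grids, ensembles, Shapley values."""

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.neighbors import KNeighborsClassifier

from bradykin.models import (HYPERPARAMETER_SPACES, MODEL_IDS, LeakageAudit,
                             WeightedResampleClassifier, build_ensembles,
                             enumerate_configs, fit_candidate_models,
                             greedy_forward_select, rank_features,
                             select_algorithm, shap_importance, tune_model)


def separable_fixture(n_subjects=10, seg_per_record=4, seed=0):
    """Binary labels decided by one well-separated feature; two records per
    subject, subject-level labels (mimics the LOSO layout)."""
    rng = np.random.default_rng(seed)
    rows, y, subj, rid = [], [], [], []
    for i in range(n_subjects):
        label = i % 2
        for rec in range(2):
            for _ in range(seg_per_record):
                rows.append([label * 10 + rng.normal(0, 0.3),
                             rng.normal(), rng.normal()])
                y.append(label)
                subj.append(f"S{i}")
                rid.append(f"S{i}_r{rec}")
    X = pd.DataFrame(rows, columns=["informative", "noise1", "noise2"])
    return X, np.array(y), np.array(subj), np.array(rid)


class TestRanking:
    def test_leaked_feature_ranks_first_with_perfect_f1(self, rng):
        y = np.tile([0, 1], 20)
        subj = np.repeat([f"S{i}" for i in range(8)], 5)
        X = pd.DataFrame({"leak": y.astype(float),
                          "noise": rng.normal(size=40)})
        scores = rank_features(X, y, subj)
        assert scores.index[0] == "leak"
        assert scores.iloc[0] == pytest.approx(1.0)

    def test_duplicated_features_score_equally(self, rng):
        y = np.tile([0, 1], 20)
        subj = np.repeat([f"S{i}" for i in range(8)], 5)
        f = rng.normal(size=40) + y
        X = pd.DataFrame({"a": f, "b": f.copy(), "z": rng.normal(size=40)})
        scores = rank_features(X, y, subj)
        assert scores["a"] == scores["b"]

    def test_noise_features_show_no_systematic_preference(self):
        """On label-free data, no pure-noise feature is persistently ranked
        on top across seeds."""
        p = 5
        first = {f"f{j}": 0 for j in range(p)}
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.tile([0, 1], 16)
            subj = np.repeat([f"S{i}" for i in range(8)], 4)
            X = pd.DataFrame({f"f{j}": rng.normal(size=32) for j in range(p)})
            first[rank_features(X, y, subj).index[0]] += 1
        assert max(first.values()) <= 14  # not always the same winner

    def test_single_class_raises(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError):
            rank_features(X, np.zeros(10), np.arange(10))


class TestGreedySelection:
    def test_trajectory_non_decreasing(self, rng):
        X, y, subj, _ = separable_fixture()
        ranked = list(rank_features(X, y, subj).index)
        _, traj = greedy_forward_select(ranked, X, y, subj)
        assert all(b >= a for a, b in zip(traj, traj[1:]))

    def test_perfect_feature_stops_growth(self):
        X, y, subj, _ = separable_fixture()
        ranked = list(rank_features(X, y, subj).index)
        selected, traj = greedy_forward_select(ranked, X, y, subj)
        assert selected == ["informative"]
        assert traj[-1] == pytest.approx(1.0)

    def test_complementary_pair_jointly_selected(self):
        """XOR-style labels: neither coordinate separates alone, together
        they do — greedy must accept the complementary feature."""
        rng = np.random.default_rng(0)
        n = 96
        a = rng.integers(0, 2, n)
        b = rng.integers(0, 2, n)
        y = a ^ b
        subj = np.repeat([f"S{i}" for i in range(8)], n // 8)
        X = pd.DataFrame({"a": a + rng.normal(0, 0.05, n),
                          "b": b + rng.normal(0, 0.05, n)})
        ranked = list(rank_features(X, y, subj).index)
        selected, traj = greedy_forward_select(ranked, X, y, subj)
        assert set(selected) == {"a", "b"}
        assert traj[-1] > traj[0] + 0.2

    def test_empty_ranking_raises(self):
        with pytest.raises(ValueError):
            greedy_forward_select([], pd.DataFrame(), [], [])


class TestTuning:
    def test_exhaustive_grid_for_low_dimensional_spaces(self):
        cfgs = enumerate_configs(HYPERPARAMETER_SPACES["SVM"], 5, seed=0)
        assert len(cfgs) == 8 * 6
        cfgs = enumerate_configs(HYPERPARAMETER_SPACES["KNN"], 5, seed=0)
        assert len(cfgs) == 5

    def test_budgeted_sampling_stays_on_grid(self):
        for model in ("DT", "RF", "GBDT", "LR"):
            space = HYPERPARAMETER_SPACES[model]
            cfgs = enumerate_configs(space, 7, seed=3, budget=10)
            assert len(cfgs) == 10
            for cfg in cfgs:
                for name, value in cfg.items():
                    grid = space[name]
                    if grid == "n_features":
                        assert 1 <= value <= 7
                    else:
                        assert value in grid

    @pytest.mark.parametrize("model_id", MODEL_IDS)
    def test_tuned_parameters_come_from_the_printed_grid(self, model_id):
        X, y, subj, _ = separable_fixture(n_subjects=6, seg_per_record=2)
        params = tune_model(X.to_numpy(), y, subj, model_id, seed=0, budget=5)
        space = HYPERPARAMETER_SPACES[model_id]
        for name, value in params.items():
            grid = space[name]
            if grid == "n_features":
                assert 1 <= value <= X.shape[1]
            else:
                assert value in grid

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            enumerate_configs({"C": []}, 3, seed=0)


class TestCandidateModels:
    def test_separable_features_ace_loso(self):
        X, y, subj, rid = separable_fixture()
        results = fit_candidate_models(X, y, subj, rid, seed=0, budget=4)
        for model_id in MODEL_IDS:
            assert results[model_id]["f1"] >= 0.95, model_id

    def test_missing_space_raises(self):
        X, y, subj, rid = separable_fixture(n_subjects=4, seg_per_record=1)
        with pytest.raises(ValueError):
            fit_candidate_models(X, y, subj, rid, spaces={"SVM": {}}, seed=0)

    def test_shuffled_labels_drop_to_chance(self):
        X, y, subj, rid = separable_fixture(n_subjects=8, seg_per_record=2)
        f1s = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            perm = rng.permutation(len(np.unique(subj)))
            relabel = {f"S{i}": int(perm[i] % 2) for i in range(len(perm))}
            y_shuf = np.array([relabel[s] for s in subj])
            if len(np.unique(y_shuf)) < 2:
                continue
            res = fit_candidate_models(X, y_shuf, subj, rid, seed=seed, budget=3)
            f1s.extend(res[m]["f1"] for m in MODEL_IDS)
        assert np.mean(f1s) < 0.75  # well below the separable fixture's 1.0

    def test_leakage_audit_clean(self):
        X, y, subj, rid = separable_fixture(n_subjects=6, seg_per_record=2)
        audit = LeakageAudit()
        fit_candidate_models(X, y, subj, rid, seed=0, budget=3, audit=audit)
        audit.assert_clean()
        audit.record("S0", "tuning", ["S0", "S1"])  # poisoned entry
        with pytest.raises(AssertionError):
            audit.assert_clean()


class TestEnsembles:
    def test_eligibility_rule_arithmetic(self):
        members = build_ensembles({"SVM": 0.80, "DT": 0.76, "KNN": 0.70})
        assert members["soft_vote"] == ["SVM", "DT"]
        assert members["hard_vote"] == ["SVM", "DT"]
        assert members["stacking"] == ["SVM", "DT"]
        assert members["adaboost"] == ["SVM"]

    def test_member_sets_invariant_to_enumeration_order(self):
        a = build_ensembles({"SVM": 0.8, "DT": 0.78, "NB": 0.5})
        b = build_ensembles({"NB": 0.5, "DT": 0.78, "SVM": 0.8})
        assert a == b

    def test_lone_eligible_model_degenerates(self):
        members = build_ensembles({"SVM": 0.9, "DT": 0.5})
        assert members["soft_vote"] == ["SVM"]

    def test_hard_vote_of_single_member_equals_the_member(self):
        from bradykin.models import _ensemble_fold_predict, _fit_predict_fold
        X, y, subj, rid = separable_fixture(n_subjects=4)
        te = subj == "S3"
        tr = ~te
        params = {"SVM": {"C": 1, "gamma": 0.1}}
        Xa = X.to_numpy()
        classes = np.unique(y)
        _, _, single_pred, _ = _fit_predict_fold(
            "SVM", params["SVM"], Xa[tr], y[tr], Xa[te], y[te], rid[te], classes, 0)
        _, _, vote_pred, _ = _ensemble_fold_predict(
            "hard_vote", ["SVM"], params, Xa[tr], y[tr], Xa[te], y[te],
            rid[te], classes, 0)
        np.testing.assert_array_equal(vote_pred, single_pred)

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError):
            build_ensembles({})


class TestSelectAlgorithm:
    @pytest.mark.parametrize("single,ensemble,expected", [
        (0.70, 0.75, "ensemble"),
        (0.75, 0.75, "single"),
        (0.75, 0.70, "single"),
    ])
    def test_rule(self, single, ensemble, expected):
        assert select_algorithm(single, ensemble) == expected


class TestWeightedResampleAdapter:
    def test_boosting_a_knn_base_works(self, rng):
        from sklearn.ensemble import AdaBoostClassifier
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] > 0).astype(int)
        clf = AdaBoostClassifier(
            estimator=WeightedResampleClassifier(KNeighborsClassifier(3),
                                                 random_state=0),
            n_estimators=5, random_state=0)
        clf.fit(X, y)
        assert clf.score(X, y) > 0.8


class TestShapImportance:
    def test_linear_model_attribution_order_and_additivity(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30), "b": rng.normal(size=30)})

        def f(Z):
            return 3.0 * np.asarray(Z)[:, 0] + 0.0 * np.asarray(Z)[:, 1]

        res = shap_importance(f, X)
        assert res.exact
        summary = res.summary()
        assert summary.loc["a", 0] > summary.loc["b", 0]
        np.testing.assert_allclose(np.abs(res.values[:, 1, 0]), 0.0, atol=1e-12)
        total = res.values.sum(axis=1)[:, 0] + res.base_values[0]
        np.testing.assert_allclose(total, f(X.to_numpy()), atol=1e-9)

    def test_classifier_local_accuracy(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        clf = RandomForestClassifier(n_estimators=10, random_state=0).fit(X, y)
        res = shap_importance(clf, X[:8], background=X)
        recon = res.values.sum(axis=1) + res.base_values
        np.testing.assert_allclose(recon, clf.predict_proba(X[:8]), atol=1e-6)

    def test_zero_variance_feature_gets_zero_attribution(self, rng):
        X = np.column_stack([rng.normal(size=30), np.full(30, 2.0)])
        y = (X[:, 0] > 0).astype(int)
        clf = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
        res = shap_importance(clf, X, background=X)
        np.testing.assert_allclose(res.values[:, 1, :], 0.0, atol=1e-12)

    def test_unfitted_model_raises(self, rng):
        with pytest.raises(NotFittedError):
            shap_importance(RandomForestClassifier(), rng.normal(size=(5, 2)))

    def test_non_finite_features_rejected(self, rng):
        clf = RandomForestClassifier(n_estimators=3, random_state=0)
        clf.fit(rng.normal(size=(10, 2)), rng.integers(0, 2, 10))
        bad = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError):
            shap_importance(clf, bad)

    def test_permutation_mode_beyond_exact_cap(self, rng):
        X = rng.normal(size=(10, 4))
        y = (X[:, 0] > 0).astype(int)
        clf = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
        res = shap_importance(clf, X[:3], background=X, max_exact_features=2,
                              n_permutations=20, seed=0)
        assert not res.exact
        assert res.values.shape == (3, 4, 2)
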