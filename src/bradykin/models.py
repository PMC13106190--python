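"""Task-specific algorithm selection: feature ranking, greedy selection,
the seven-model zoo with fixed hyperparameter grids, four ensemble
constructions with the 0.05-eligibility rule, and Shapley attributions.

The candidate models are SVM, decision tree (DT), random forest (RF),
gradient-boosted trees (GBDT), logistic regression (LR), Gaussian naive
Bayes (NB) and k-nearest neighbours (KNN).  Hyperparameters are tuned on
training folds only: spaces with at most two dimensions are searched
exhaustively, larger spaces by a seeded random draw of a fixed budget of
configurations, both scored by subject-grouped cross-validated weighted F1.

The optimal single model competes against four ensembles: AdaBoost on the
optimal model alone, soft voting, hard voting and stacking over the optimal
model plus every model whose F1 lies within 0.05 of the best.  A tie goes to
the single model (lower training complexity).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier, StackingClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import GroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted, has_fit_parameter

from .evaluate import (_fast_metric, aggregate_majority, loso_splits,
                       smote_balance)

__all__ = [
    "MODEL_IDS",
    "HYPERPARAMETER_SPACES",
    "LeakageAudit",
    "make_estimator",
    "enumerate_configs",
    "tune_model",
    "rank_features",
    "greedy_forward_select",
    "fit_candidate_models",
    "build_ensembles",
    "evaluate_ensembles",
    "select_algorithm",
    "AlgorithmChoice",
    "shap_importance",
    "ShapResult",
]

MODEL_IDS = ("SVM", "DT", "RF", "GBDT", "LR", "NB", "KNN")
ENSEMBLE_KINDS = ("adaboost", "soft_vote", "hard_vote", "stacking")

_TREE_GRID = {
    "max_depth": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30],
    "min_samples_split": [2, 3, 4, 5, 6, 7, 8, 9, 10],
    "min_samples_leaf": [2, 3, 4, 5, 6, 7, 8, 9, 10],
    "max_features": "n_features",  # resolved to 1..n_features at tune time
}

#: Hyperparameter grids searched per model (`max_features` expands to the
#: feature count at tune time).
HYPERPARAMETER_SPACES: dict[str, dict] = {
    "SVM": {
        "C": [0.001, 0.01, 0.1, 1, 10, 50, 100, 200],
        "gamma": [0.001, 0.01, 0.1, 1, 5, 10],
    },
    "DT": dict(_TREE_GRID),
    "RF": {**_TREE_GRID,
           "n_estimators": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 15, 20, 30]},
    "GBDT": {**_TREE_GRID,
             "n_estimators": [1, 2, 3, 4, 5, 6, 7, 8, 10, 15, 20, 30],
             "learning_rate": [0.001, 0.005, 0.01, 0.05, 0.1, 0.5]},
    "LR": {
        "penalty": ["l2", "none"],
        "solver": ["lbfgs", "newton-cg", "sag", "saga"],
        "C": [0.001, 0.005, 0.01, 0.05, 0.1, 0.5, 1, 2, 5, 10, 100],
    },
    "KNN": {"n_neighbors": [1, 2, 3, 4, 5]},
    "NB": {"var_smoothing": [1, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005,
                             0.002, 0.001, 0.0005, 0.0002, 0.0001]},
}


class LeakageAudit:
    """Records which subjects each protocol phase touched, per LOSO fold.

    ``assert_clean()`` raises if any training-side phase (tuning, feature
    selection, SMOTE, fitting) of a fold saw the fold's held-out subject.
    """

    def __init__(self) -> None:
        self.entries: list[tuple[object, str, frozenset]] = []

    def record(self, fold_subject, phase: str, subjects) -> None:
        self.entries.append((fold_subject, phase, frozenset(subjects)))

    def assert_clean(self) -> None:
        for fold_subject, phase, subjects in self.entries:
            if fold_subject in subjects:
                raise AssertionError(
                    f"leakage: phase {phase!r} of fold {fold_subject!r} "
                    f"touched the held-out subject")


class WeightedResampleClassifier(BaseEstimator, ClassifierMixin):
    """Adapter giving sample_weight support to any classifier via a weighted
    bootstrap resample of the training set (needed to boost e.g. KNN)."""

    def __init__(self, estimator=None, random_state: int = 0):
        self.estimator = estimator
        self.random_state = random_state

    def fit(self, X, y, sample_weight=None):
        est = clone(self.estimator)
        if sample_weight is not None:
            w = np.asarray(sample_weight, dtype=float)
            w = w / w.sum()
            # counter makes successive boosting rounds draw fresh resamples
            self._fit_count = getattr(self, "_fit_count", 0) + 1
            rng = np.random.default_rng(self.random_state + self._fit_count)
            idx = rng.choice(len(y), size=len(y), replace=True, p=w)
            X, y = np.asarray(X)[idx], np.asarray(y)[idx]
        est.fit(X, y)
        self.estimator_ = est
        self.classes_ = est.classes_
        return self

    def predict(self, X):
        return self.estimator_.predict(X)

    def predict_proba(self, X):
        return self.estimator_.predict_proba(X)


def _bare_classifier(model_id: str, params: dict, seed: int, probability: bool):
    p = dict(params)
    if model_id == "SVM":
        return SVC(C=p.get("C", 1.0), gamma=p.get("gamma", "scale"),
                   probability=probability, random_state=seed)
    if model_id == "DT":
        return DecisionTreeClassifier(random_state=seed, **p)
    if model_id == "RF":
        return RandomForestClassifier(random_state=seed, **p)
    if model_id == "GBDT":
        return GradientBoostingClassifier(random_state=seed, **p)
    if model_id == "LR":
        penalty = p.get("penalty", "l2")
        return LogisticRegression(
            penalty=None if penalty == "none" else penalty,
            solver=p.get("solver", "lbfgs"), C=p.get("C", 1.0),
            max_iter=2000, random_state=seed)
    if model_id == "KNN":
        return KNeighborsClassifier(**p)
    if model_id == "NB":
        return GaussianNB(**p)
    raise ValueError(f"unknown model id {model_id!r}")


def make_estimator(model_id: str, params: dict | None = None, seed: int = 0,
                   probability: bool = True) -> Pipeline:
    """Standardisation + classifier pipeline for one model id."""
    clf = _bare_classifier(model_id, params or {}, seed, probability)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def base_svm() -> Pipeline:
    """Untuned base classifier used for feature ranking and greedy selection."""
    return make_estimator("SVM", {"C": 1.0, "gamma": "scale"}, probability=False)


def enumerate_configs(space: dict, n_features: int, seed: int,
                      budget: int = 10) -> list[dict]:
    """Concrete hyperparameter settings drawn from a fixed grid.

    Spaces with <= 2 dimensions are enumerated exhaustively; larger spaces
    yield a seeded random draw of `budget` distinct settings.  Values never
    leave the grid.
    """
    grids = {}
    for name, values in space.items():
        if values == "n_features":
            values = list(range(1, n_features + 1))
        if not values:
            raise ValueError(f"empty grid for {name!r}")
        grids[name] = list(values)
    names = sorted(grids)
    sizes = [len(grids[n]) for n in names]
    total = math.prod(sizes)
    if len(names) <= 2 or total <= budget:
        combos = list(itertools.product(*(range(s) for s in sizes)))
    else:
        rng = np.random.default_rng(seed)
        flat = rng.choice(total, size=budget, replace=False)
        combos = [np.unravel_index(i, sizes) for i in sorted(flat)]
    return [{n: grids[n][c[j]] for j, n in enumerate(names)} for c in combos]


def _cv_fold_data(X, y, groups, n_splits: int = 3,
                  smote_seed: int | None = None) -> list[tuple]:
    """Standardised (train-fitted) grouped-CV fold data as plain arrays.

    Precomputing the folds once — SMOTE, scaling — lets the tuning and
    selection loops fit bare classifiers on numpy arrays, avoiding repeated
    resampling and per-fit framework overhead.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = np.asarray(groups)
    k = min(n_splits, len(np.unique(groups)))
    if k < 2:
        raise ValueError("need at least 2 groups for grouped CV")
    folds = []
    for tr, va in GroupKFold(n_splits=k).split(X, y, groups):
        X_tr, y_tr = X[tr], y[tr]
        if smote_seed is not None and len(np.unique(y_tr)) > 1:
            counts = np.unique(y_tr, return_counts=True)[1]
            if counts.min() >= 2:
                X_tr, y_tr = smote_balance(X_tr, y_tr, seed=smote_seed)
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        folds.append(((X_tr - mu) / sd, y_tr, (X[va] - mu) / sd, y[va]))
    return folds


def _oof_f1(fold_data: list[tuple], make_clf, cols=None) -> float:
    """Weighted F1 over concatenated out-of-fold predictions."""
    oof_true, oof_pred = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for X_tr, y_tr, X_va, y_va in fold_data:
            if cols is not None:
                X_tr, X_va = X_tr[:, cols], X_va[:, cols]
            if len(np.unique(y_tr)) < 2:
                continue
            clf = make_clf()
            try:
                clf.fit(X_tr, y_tr)
                pred = clf.predict(X_va)
            except Exception:
                continue
            oof_true.append(y_va)
            oof_pred.append(pred)
    if not oof_true:
        return 0.0
    t = np.concatenate(oof_true)
    p = np.concatenate(oof_pred)
    return _fast_metric("f1", t, p, None, np.unique(np.concatenate([t, p])))


def _grouped_cv_f1(X, y, groups, make_clf, n_splits: int = 3,
                   smote_seed: int | None = None) -> float:
    """Weighted F1 of a classifier under subject-grouped CV (standardised)."""
    return _oof_f1(_cv_fold_data(X, y, groups, n_splits, smote_seed), make_clf)


def _bare_svm():
    return SVC(C=1.0, gamma="scale")


# ------------------------------------------------------- feature selection

def rank_features(features: pd.DataFrame, labels, subject_ids, seed: int = 0,
                  n_splits: int = 3) -> pd.Series:
    """Score each feature by its single-feature weighted F1 with the base SVM
    under subject-grouped CV; return scores sorted descending (ties broken
    alphabetically for determinism)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("feature ranking needs at least 2 classes")
    fold_data = _cv_fold_data(features.to_numpy(dtype=float), y, subject_ids,
                              n_splits)
    scores = {col: _oof_f1(fold_data, _bare_svm, cols=[j])
              for j, col in enumerate(features.columns)}
    s = pd.Series(scores)
    order = sorted(s.index, key=lambda c: (-s[c], c))
    return s.loc[order]


def greedy_forward_select(ranked: list[str], features: pd.DataFrame, labels,
                          subject_ids, seed: int = 0, n_splits: int = 3,
                          max_candidates: int | None = None
                          ) -> tuple[list[str], list[float]]:
    """Greedy forward selection in rank order.

    Starts from the top-ranked feature; each next feature is kept iff the
    subject-grouped CV weighted F1 of the base SVM strictly improves.
    Returns the selected subset and the (non-decreasing) F1 trajectory.
    """
    if not ranked:
        raise ValueError("ranked feature list must be non-empty")
    y = np.asarray(labels)
    fold_data = _cv_fold_data(features.to_numpy(dtype=float), y, subject_ids,
                              n_splits)
    col_of = {c: j for j, c in enumerate(features.columns)}
    candidates = list(ranked if max_candidates is None else ranked[:max_candidates])
    selected = [candidates[0]]
    best = _oof_f1(fold_data, _bare_svm, cols=[col_of[selected[0]]])
    trajectory = [best]
    for feat in candidates[1:]:
        if best >= 1.0:
            break
        trial = selected + [feat]
        score = _oof_f1(fold_data, _bare_svm, cols=[col_of[f] for f in trial])
        if score > best:
            selected = trial
            best = score
            trajectory.append(best)
    return selected, trajectory


# ------------------------------------------------------------------ tuning

def tune_model(X, y, groups, model_id: str, space: dict | None = None,
               seed: int = 0, budget: int = 10, n_splits: int = 3) -> dict:
    """Pick the best grid setting by grouped-CV weighted F1 on training data.

    SMOTE is applied inside each inner training fold.  Ties resolve to the
    first configuration in the deterministic enumeration order.
    """
    space = HYPERPARAMETER_SPACES[model_id] if space is None else space
    X = np.asarray(X, dtype=float)
    configs = enumerate_configs(space, X.shape[1], seed, budget)
    fold_data = _cv_fold_data(X, y, groups, n_splits, smote_seed=seed)
    scores = np.empty(len(configs))
    for i, cfg in enumerate(configs):
        scores[i] = _oof_f1(
            fold_data,
            lambda cfg=cfg: _bare_classifier(model_id, cfg, seed, probability=False))
    return configs[int(np.argmax(scores))]


# ---------------------------------------------------------- LOSO evaluation

@dataclass
class FoldPredictions:
    """Segment- and record-level test predictions of one LOSO fold."""

    test_subject: object
    record_ids: list[str]
    record_true: np.ndarray
    record_pred: np.ndarray
    record_prob: np.ndarray
    params: dict = field(default_factory=dict)


def _aligned_proba(est, X, classes: np.ndarray) -> np.ndarray:
    p = est.predict_proba(X)
    out = np.zeros((len(X), len(classes)))
    col = {c: j for j, c in enumerate(classes)}
    for j, c in enumerate(est.classes_):
        out[:, col[c]] = p[:, j]
    return out


def _vote_records(record_ids, y_true, seg_pred, seg_prob):
    """Majority-vote segment predictions into record predictions; record
    probability is the mean of its segments' probability rows."""
    recs = sorted(set(record_ids))
    rec_true, rec_pred, rec_prob = [], [], []
    rid = np.asarray(record_ids)
    for r in recs:
        m = rid == r
        rec_true.append(int(np.asarray(y_true)[m][0]))
        rec_pred.append(aggregate_majority(np.asarray(seg_pred)[m]))
        rec_prob.append(np.asarray(seg_prob)[m].mean(axis=0))
    return recs, np.array(rec_true), np.array(rec_pred), np.vstack(rec_prob)


def _fit_predict_fold(model_id, params, X_tr, y_tr, X_te, y_te, rid_te,
                      classes, seed):
    X_bal, y_bal = smote_balance(X_tr, y_tr, seed=seed)
    est = make_estimator(model_id, params, seed, probability=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X_bal, y_bal)
        seg_pred = est.predict(X_te)
        seg_prob = _aligned_proba(est, X_te, classes)
    return _vote_records(rid_te, y_te, seg_pred, seg_prob)


def fit_candidate_models(features: pd.DataFrame, labels, subject_ids,
                         record_ids, spaces: dict | None = None, seed: int = 0,
                         budget: int = 10, inner_splits: int = 3,
                         audit: LeakageAudit | None = None) -> dict:
    """LOSO-evaluate all seven models with nested, training-fold-only tuning.

    Returns ``{model_id: {"f1": record-level weighted F1, "folds": [...],
    "record_true"/"record_pred"/"record_prob"/"record_ids": ...}}``.
    """
    spaces = HYPERPARAMETER_SPACES if spaces is None else spaces
    missing = [m for m in MODEL_IDS if m not in spaces]
    if missing:
        raise ValueError(f"missing hyperparameter space for {missing}")
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    subj = np.asarray(subject_ids)
    rid = np.asarray(record_ids)
    classes = np.unique(y)

    results: dict[str, dict] = {m: {"folds": []} for m in MODEL_IDS}
    for train_subjects, test_subject in loso_splits(subj):
        tr = np.isin(subj, train_subjects)
        te = subj == test_subject
        if audit is not None:
            audit.record(test_subject, "tuning", subj[tr])
            audit.record(test_subject, "smote", subj[tr])
        for model_id in MODEL_IDS:
            params = tune_model(X[tr], y[tr], subj[tr], model_id,
                                spaces[model_id], seed, budget, inner_splits)
            recs, r_true, r_pred, r_prob = _fit_predict_fold(
                model_id, params, X[tr], y[tr], X[te], y[te], rid[te],
                classes, seed)
            results[model_id]["folds"].append(FoldPredictions(
                test_subject, recs, r_true, r_pred, r_prob, params))
    for model_id in MODEL_IDS:
        folds = results[model_id]["folds"]
        results[model_id]["record_ids"] = sum((f.record_ids for f in folds), [])
        results[model_id]["record_true"] = np.concatenate([f.record_true for f in folds])
        results[model_id]["record_pred"] = np.concatenate([f.record_pred for f in folds])
        results[model_id]["record_prob"] = np.vstack([f.record_prob for f in folds])
        results[model_id]["f1"] = f1_score(
            results[model_id]["record_true"], results[model_id]["record_pred"],
            average="weighted", zero_division=0)
    return results


# --------------------------------------------------------------- ensembles

def build_ensembles(model_scores: dict[str, float],
                    eligibility_delta: float = 0.05) -> dict[str, list[str]]:
    """Member sets of the four ensembles from per-model F1 scores.

    AdaBoost wraps only the optimal model; the voting and stacking ensembles
    combine the optimal model with every model whose F1 differs from the best
    by strictly less than `eligibility_delta`.  Member order (best first,
    then descending F1, ties alphabetical) is independent of the enumeration
    order of `model_scores`.
    """
    if not model_scores:
        raise ValueError("need at least one tuned model")
    order = sorted(model_scores, key=lambda m: (-model_scores[m], m))
    best = order[0]
    best_f1 = model_scores[best]
    members = [m for m in order
               if model_scores[best] - model_scores[m] < eligibility_delta]
    assert members[0] == best
    return {"adaboost": [best], "soft_vote": list(members),
            "hard_vote": list(members), "stacking": list(members)}


def _severe_argmax(prob: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Argmax over classes, ties resolved toward the higher (severer) class."""
    best = prob.max(axis=1, keepdims=True)
    is_best = prob >= best - 1e-12
    # last column among the tied maxima
    idx = is_best.shape[1] - 1 - np.argmax(is_best[:, ::-1], axis=1)
    return classes[idx]


def _ensemble_fold_predict(kind, members, fold_params, X_tr, y_tr, X_te, y_te,
                           rid_te, classes, seed):
    X_bal, y_bal = smote_balance(X_tr, y_tr, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if kind == "adaboost":
            base = _bare_classifier(members[0], fold_params[members[0]], seed,
                                    probability=True)
            if not has_fit_parameter(base, "sample_weight"):
                base = WeightedResampleClassifier(base, random_state=seed)
            est = Pipeline([
                ("scale", StandardScaler()),
                ("clf", AdaBoostClassifier(estimator=base, n_estimators=50,
                                           random_state=seed)),
            ])
            try:
                est.fit(X_bal, y_bal)
            except ValueError:
                # boosting is infeasible when the base errs worse than chance
                # on the reweighted sample; degrade to the base model alone
                est = make_estimator(members[0], fold_params[members[0]],
                                     seed, probability=True)
                est.fit(X_bal, y_bal)
            seg_pred = est.predict(X_te)
            seg_prob = _aligned_proba(est, X_te, classes)
        elif kind == "stacking":
            ests = [(m, make_estimator(m, fold_params[m], seed, probability=True))
                    for m in members]
            est = StackingClassifier(
                estimators=ests, stack_method="predict_proba", cv=3,
                final_estimator=LogisticRegression(max_iter=2000, random_state=seed))
            est.fit(X_bal, y_bal)
            seg_pred = est.predict(X_te)
            seg_prob = _aligned_proba(est, X_te, classes)
        elif kind in ("soft_vote", "hard_vote"):
            probs, preds = [], []
            for m in members:
                est = make_estimator(m, fold_params[m], seed, probability=True)
                est.fit(X_bal, y_bal)
                probs.append(_aligned_proba(est, X_te, classes))
                preds.append(est.predict(X_te))
            if kind == "soft_vote":
                seg_prob = np.mean(probs, axis=0)
            else:
                # vote fractions double as pseudo-probabilities
                votes = np.stack(preds)
                seg_prob = np.stack([(votes == c).mean(axis=0) for c in classes], axis=1)
            seg_pred = _severe_argmax(seg_prob, classes)
        else:
            raise ValueError(f"unknown ensemble kind {kind!r}")
    return _vote_records(rid_te, y_te, seg_pred, seg_prob)


def evaluate_ensembles(features: pd.DataFrame, labels, subject_ids, record_ids,
                       single_results: dict, eligibility_delta: float = 0.05,
                       seed: int = 0) -> dict:
    """LOSO-evaluate the four ensembles built from the single-model results.

    Member hyperparameters are the per-fold tuned settings cached during the
    single-model pass, so ensembles see exactly the same nested protocol.
    """
    model_scores = {m: single_results[m]["f1"] for m in single_results}
    member_sets = build_ensembles(model_scores, eligibility_delta)
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    subj = np.asarray(subject_ids)
    rid = np.asarray(record_ids)
    classes = np.unique(y)
    any_model = next(iter(single_results))
    fold_subjects = [f.test_subject for f in single_results[any_model]["folds"]]

    out: dict[str, dict] = {}
    for kind, members in member_sets.items():
        folds = []
        for i, test_subject in enumerate(fold_subjects):
            tr = subj != test_subject
            te = ~tr
            fold_params = {m: single_results[m]["folds"][i].params for m in members}
            recs, r_true, r_pred, r_prob = _ensemble_fold_predict(
                kind, members, fold_params, X[tr], y[tr], X[te], y[te],
                rid[te], classes, seed)
            folds.append(FoldPredictions(test_subject, recs, r_true, r_pred,
                                         r_prob, fold_params))
        res = {"folds": folds, "members": members,
               "record_ids": sum((f.record_ids for f in folds), []),
               "record_true": np.concatenate([f.record_true for f in folds]),
               "record_pred": np.concatenate([f.record_pred for f in folds]),
               "record_prob": np.vstack([f.record_prob for f in folds])}
        res["f1"] = f1_score(res["record_true"], res["record_pred"],
                             average="weighted", zero_division=0)
        out[kind] = res
    return out


@dataclass(frozen=True)
class AlgorithmChoice:
    kind: str  # "single" or one of ENSEMBLE_KINDS
    name: str  # model id or ensemble kind
    members: tuple[str, ...]
    f1_single: float
    f1_ensemble: float


def select_algorithm(single_best_f1: float, ensemble_best_f1: float) -> str:
    """Single model vs ensemble: higher F1 wins, an exact tie goes to the
    single model (lower training complexity)."""
    return "ensemble" if ensemble_best_f1 > single_best_f1 else "single"


# -------------------------------------------------------------------- SHAP

@dataclass
class ShapResult:
    """Per-sample Shapley attributions of a model's output.

    ``values`` has shape (n_samples, n_features, n_outputs); local accuracy
    holds: ``values[i].sum(axis=0) + base_values == f(x_i)`` (exactly, up to
    float round-off, in exact mode).
    """

    values: np.ndarray
    base_values: np.ndarray
    feature_names: list[str]
    output_names: list
    exact: bool

    def summary(self) -> pd.DataFrame:
        """Mean |attribution| per feature per output class (for bar charts)."""
        mean_abs = np.abs(self.values).mean(axis=0)
        return pd.DataFrame(mean_abs, index=self.feature_names,
                            columns=self.output_names)


def _model_fn(model):
    if callable(model) and not isinstance(model, BaseEstimator):
        f = model
        names = None
    elif hasattr(model, "predict_proba"):
        check_is_fitted(model)
        f = model.predict_proba
        names = list(getattr(model, "classes_", []))
    elif hasattr(model, "decision_function"):
        check_is_fitted(model)
        f = model.decision_function
        names = None
    else:
        check_is_fitted(model)
        f = model.predict
        names = None

    def wrapped(Z):
        out = np.asarray(f(Z), dtype=float)
        return out[:, None] if out.ndim == 1 else out

    return wrapped, names


def shap_importance(model, features, background=None,
                    max_exact_features: int = 10, n_permutations: int = 64,
                    seed: int = 0) -> ShapResult:
    """Interventional Shapley attributions of a fitted model.

    Feature ``j``'s attribution for a sample is the Shapley value of the game
    ``v(S) = E_background[f(x_S, z_{~S})]``.  With at most
    `max_exact_features` features every coalition is enumerated (exact
    Shapley values, local accuracy to float precision); beyond that a seeded
    permutation-sampling estimate with `n_permutations` draws is used.
    """
    f, output_names = _model_fn(model)
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = [f"f{j}" for j in range(X.shape[1])]
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix must be finite")
    bg = X if background is None else np.asarray(background, dtype=float)
    if len(bg) > 100:
        rng = np.random.default_rng(seed)
        bg = bg[rng.choice(len(bg), size=100, replace=False)]
    n, p = X.shape
    nbg = len(bg)

    def v_of_mask(mask_bits: np.ndarray) -> np.ndarray:
        # (n, n_outputs): expectation of f with masked features set to x
        Z = np.repeat(bg[None, :, :], n, axis=0)  # (n, nbg, p)
        for j in np.flatnonzero(mask_bits):
            Z[:, :, j] = X[:, j][:, None]
        out = f(Z.reshape(n * nbg, p))
        return out.reshape(n, nbg, -1).mean(axis=1)

    if output_names is None or not output_names:
        output_names = list(range(v_of_mask(np.zeros(p, bool)).shape[1]))

    if p <= max_exact_features:
        vs = {}
        for mask in range(2**p):
            bits = np.array([(mask >> j) & 1 for j in range(p)], dtype=bool)
            vs[mask] = v_of_mask(bits)
        fact = [math.factorial(i) for i in range(p + 1)]
        w = [fact[s] * fact[p - 1 - s] / fact[p] for s in range(p)]
        phi = np.zeros((n, p, len(output_names)))
        for mask in range(2**p):
            s = bin(mask).count("1")
            for j in range(p):
                if mask & (1 << j):
                    continue
                phi[:, j, :] += w[s] * (vs[mask | (1 << j)] - vs[mask])
        base = vs[0][0]
        exact = True
    else:
        rng = np.random.default_rng(seed)
        phi = np.zeros((n, p, len(output_names)))
        base = v_of_mask(np.zeros(p, bool))[0]
        for _ in range(n_permutations):
            perm = rng.permutation(p)
            bits = np.zeros(p, dtype=bool)
            v_prev = v_of_mask(bits)
            for j in perm:
                bits[j] = True
                v_new = v_of_mask(bits)
                phi[:, j, :] += v_new - v_prev
                v_prev = v_new
        phi /= n_permutations
        exact = False
    return ShapResult(values=phi, base_values=base, feature_names=names,
                      output_names=output_names, exact=exact)
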