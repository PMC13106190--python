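"""End-to-end orchestration: simulate -> preprocess -> peaks -> features ->
model selection -> LOSO evaluation, one scoring scenario per run.

The protocol is fully nested by default: inside every LOSO fold, feature
ranking, greedy forward selection and hyperparameter tuning see only the
training subjects.  ``global_selection=True`` instead performs feature
selection once on the full dataset before the LOSO loop — a flatter, faster
protocol that is optimistically biased (off by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score

from . import models as _m
from .evaluate import (SCENARIOS, Scenario, bootstrap_ci, compute_metrics,
                       loso_splits, map_labels, mcnemar_compare)
from .features import features_dataframe, feature_names, META_COLUMNS
from .models import (HYPERPARAMETER_SPACES, LeakageAudit, MODEL_IDS,
                     build_ensembles, greedy_forward_select, rank_features,
                     select_algorithm, tune_model)
from .peaks import PeakFilterConfig
from .preprocess import SegmentationConfig, preprocess_recording
from .simulate import generate_cohort

__all__ = [
    "DEFAULT_SCORE_DISTRIBUTION",
    "extract_task_features",
    "run_task_pipeline",
    "run_full_study",
]

#: Pooled patient + control composition of the FT-R test session of a
#: 29-participant cohort: counts (6, 14, 3, 6, 0) for scores 0-4.
DEFAULT_SCORE_DISTRIBUTION: dict[int, float] = {0: 6 / 29, 1: 14 / 29,
                                                2: 3 / 29, 3: 6 / 29}

_METRICS = ("accuracy", "precision", "recall", "f1", "rmse", "auc")


def extract_task_features(recordings, task: str, side: str,
                          seg_config: SegmentationConfig | None = None,
                          peak_config: PeakFilterConfig | None = None,
                          denoise: bool = True) -> pd.DataFrame:
    """Preprocess, detect peaks and extract features for one task and side."""
    seg_config = seg_config or SegmentationConfig()
    peak_config = peak_config or PeakFilterConfig()
    recs = [r for r in recordings if r.task == task and r.side == side]
    if not recs:
        raise ValueError(f"no recordings for task {task!r}, side {side!r}")
    segments = []
    for r in recs:
        segments.extend(preprocess_recording(r, seg_config, denoise=denoise))
    return features_dataframe(segments, peak_config)


def _record_f1(res: dict) -> float:
    return float(f1_score(res["record_true"], res["record_pred"],
                          average="weighted", zero_division=0))


def run_task_pipeline(feature_table: pd.DataFrame, scenario: Scenario | str,
                      seed: int = 0, *, budget: int = 10, inner_splits: int = 3,
                      max_greedy: int = 20, bootstrap_reps: int = 2000,
                      eligibility_delta: float = 0.05,
                      global_selection: bool = False,
                      spaces: dict | None = None,
                      audit: LeakageAudit | None = None) -> dict:
    """Select and evaluate the task-specific algorithm for one scenario.

    `feature_table` is the output of :func:`extract_task_features` (metadata
    columns + the feature schema).  Returns a JSON-serialisable report:
    per-model and per-ensemble record-level weighted F1, the single-vs-
    ensemble choice, metrics of the chosen algorithm with stratified
    bootstrap CIs, and Bonferroni-corrected McNemar comparisons against
    every alternative.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    spaces = HYPERPARAMETER_SPACES if spaces is None else {
        **HYPERPARAMETER_SPACES, **spaces}
    feat_cols = [c for c in feature_table.columns if c not in META_COLUMNS]
    X_df = feature_table[feat_cols]
    y = map_labels(feature_table["score_raw"].to_numpy(), scenario)
    subj = feature_table["subject_id"].to_numpy()
    rid = feature_table["record_id"].to_numpy()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("scenario leaves a single class; nothing to predict")

    audit = audit if audit is not None else LeakageAudit()

    # reference selection on the full cohort: the deployable feature set
    ranked_all = rank_features(X_df, y, subj, seed)
    selected_all, trajectory_all = greedy_forward_select(
        list(ranked_all.index), X_df, y, subj, seed, max_candidates=max_greedy)

    folds = loso_splits(subj)
    single: dict[str, dict] = {m: {"folds": []} for m in MODEL_IDS}
    fold_features: list[list[str]] = []
    Xall = X_df.to_numpy(dtype=float)
    col_idx = {c: j for j, c in enumerate(feat_cols)}

    for train_subjects, test_subject in folds:
        tr = subj != test_subject
        te = ~tr
        if global_selection:
            feats = selected_all
        else:
            ranked = rank_features(X_df[tr], y[tr], subj[tr], seed)
            feats, _ = greedy_forward_select(
                list(ranked.index), X_df[tr], y[tr], subj[tr], seed,
                max_candidates=max_greedy)
        audit.record(test_subject, "feature_selection",
                     subj[tr] if not global_selection else subj)
        fold_features.append(feats)
        cols = [col_idx[c] for c in feats]
        Xtr, Xte = Xall[np.ix_(tr, cols)], Xall[np.ix_(te, cols)]
        audit.record(test_subject, "tuning", subj[tr])
        audit.record(test_subject, "smote", subj[tr])
        for model_id in MODEL_IDS:
            params = tune_model(Xtr, y[tr], subj[tr], model_id,
                                spaces[model_id], seed, budget, inner_splits)
            recs, r_true, r_pred, r_prob = _m._fit_predict_fold(
                model_id, params, Xtr, y[tr], Xte, y[te], rid[te], classes, seed)
            single[model_id]["folds"].append(_m.FoldPredictions(
                test_subject, recs, r_true, r_pred, r_prob, params))

    for model_id in MODEL_IDS:
        fl = single[model_id]["folds"]
        single[model_id]["record_ids"] = sum((f.record_ids for f in fl), [])
        single[model_id]["record_true"] = np.concatenate([f.record_true for f in fl])
        single[model_id]["record_pred"] = np.concatenate([f.record_pred for f in fl])
        single[model_id]["record_prob"] = np.vstack([f.record_prob for f in fl])
        single[model_id]["f1"] = _record_f1(single[model_id])

    model_scores = {m: single[m]["f1"] for m in MODEL_IDS}
    member_sets = build_ensembles(model_scores, eligibility_delta)
    ensembles: dict[str, dict] = {}
    for kind, members in member_sets.items():
        efolds = []
        for i, (train_subjects, test_subject) in enumerate(folds):
            tr = subj != test_subject
            te = ~tr
            cols = [col_idx[c] for c in fold_features[i]]
            fold_params = {m: single[m]["folds"][i].params for m in members}
            recs, r_true, r_pred, r_prob = _m._ensemble_fold_predict(
                kind, members, fold_params, Xall[np.ix_(tr, cols)], y[tr],
                Xall[np.ix_(te, cols)], y[te], rid[te], classes, seed)
            efolds.append(_m.FoldPredictions(test_subject, recs, r_true,
                                             r_pred, r_prob, fold_params))
        res = {"folds": efolds, "members": members,
               "record_ids": sum((f.record_ids for f in efolds), []),
               "record_true": np.concatenate([f.record_true for f in efolds]),
               "record_pred": np.concatenate([f.record_pred for f in efolds]),
               "record_prob": np.vstack([f.record_prob for f in efolds])}
        res["f1"] = _record_f1(res)
        ensembles[kind] = res

    best_single = min(MODEL_IDS, key=lambda m: (-single[m]["f1"], m))
    best_ensemble = min(ensembles, key=lambda k: (-ensembles[k]["f1"], k))
    kind = select_algorithm(single[best_single]["f1"],
                            ensembles[best_ensemble]["f1"])
    if kind == "single":
        chosen_name, chosen = best_single, single[best_single]
        chosen_members = (best_single,)
    else:
        chosen_name, chosen = best_ensemble, ensembles[best_ensemble]
        chosen_members = tuple(ensembles[best_ensemble]["members"])

    audit.assert_clean()

    metrics = {}
    for metric in _METRICS:
        point, lo, hi = bootstrap_ci(
            chosen["record_true"], chosen["record_pred"], chosen["record_prob"],
            metric, B=bootstrap_reps, seed=seed, classes=classes)
        metrics[metric] = {"value": point, "ci_lower": lo, "ci_upper": hi}

    alternatives = ([m for m in MODEL_IDS if m != chosen_name] +
                    [k for k in ensembles if k != chosen_name])
    mcnemar = {}
    for alt in alternatives:
        other = single[alt] if alt in single else ensembles[alt]
        res = mcnemar_compare(chosen["record_true"], chosen["record_pred"],
                              other["record_pred"],
                              n_comparisons=len(alternatives))
        mcnemar[alt] = {"b": res.b, "c": res.c, "statistic": res.statistic,
                        "p_value": res.p_value, "significant": res.significant}

    return {
        "scenario": scenario.id,
        "seed": seed,
        "n_subjects": int(len(set(subj))),
        "n_records": int(len(set(rid))),
        "n_segments": int(len(feature_table)),
        "classes": [int(c) for c in classes],
        "selected_features": selected_all,
        "selection_trajectory": [float(v) for v in trajectory_all],
        "model_f1": {m: float(single[m]["f1"]) for m in MODEL_IDS},
        "ensemble_f1": {k: float(ensembles[k]["f1"]) for k in ensembles},
        "ensemble_members": {k: list(ensembles[k]["members"]) for k in ensembles},
        "choice": {
            "kind": kind, "name": chosen_name, "members": list(chosen_members),
            "f1_single": float(single[best_single]["f1"]),
            "f1_ensemble": float(ensembles[best_ensemble]["f1"]),
        },
        "metrics": metrics,
        "mcnemar": mcnemar,
        "records": {
            "ids": list(chosen["record_ids"]),
            "true": [int(v) for v in chosen["record_true"]],
            "pred": [int(v) for v in chosen["record_pred"]],
        },
    }


def run_full_study(n_subjects: int = 29,
                   score_distribution: dict[int, float] | None = None,
                   seed: int = 0, task: str = "FT", side: str = "R",
                   scenarios: tuple[str, ...] = ("precise", "abnormal", "critical"),
                   **pipeline_kwargs) -> dict[str, dict]:
    """Simulate a cohort and run the task pipeline for each scenario.

    The cohort uses the default severity profiles with a deterministic score
    composition (largest-remainder allocation of `score_distribution`,
    default: the pooled 29-participant FT-R composition).  Features are
    extracted once and shared across scenarios.
    """
    dist = DEFAULT_SCORE_DISTRIBUTION if score_distribution is None else score_distribution
    cohort = generate_cohort(n_subjects, dist, seed, exact_counts=True)
    table = extract_task_features(cohort, task, side)
    return {s: run_task_pipeline(table, s, seed, **pipeline_kwargs)
            for s in scenarios}
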