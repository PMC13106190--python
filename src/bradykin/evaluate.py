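"""Scoring scenarios, LOSO protocol, SMOTE balancing, metrics and statistics.

Three clinically motivated scenarios map the (4-folded-into-3) ordinal score
onto the classification target:

* ``precise``  — four classes, 0 vs 1 vs 2 vs 3 (treatment management);
* ``abnormal`` — 0 vs {1,2,3} (screening for bradykinesia onset);
* ``critical`` — {0,1,2} vs 3 (tracking severe impairment).

Evaluation is leave-one-subject-out: one fold per participant, the training
folds oversampled with SMOTE until every class holds an equal share (1/k of
the training set).  Record-level predictions are the majority vote of a
record's segment predictions, ties broken toward the more severe class
(clinically conservative).  Metric uncertainty comes from a stratified
bootstrap (resampling records within each true-class stratum), and paired
algorithms are compared with McNemar's test under Bonferroni correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spst
from sklearn.metrics import (accuracy_score, precision_recall_fscore_support,
                             roc_auc_score)
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "SCENARIOS",
    "map_labels",
    "loso_splits",
    "smote_balance",
    "aggregate_majority",
    "compute_metrics",
    "bootstrap_ci",
    "mcnemar_compare",
    "McNemarResult",
]


@dataclass(frozen=True)
class Scenario:
    id: str
    mapping: tuple[int, int, int, int]  # class index for mapped scores 0..3

    @property
    def n_classes(self) -> int:
        return len(set(self.mapping))


SCENARIOS: dict[str, Scenario] = {
    "precise": Scenario("precise", (0, 1, 2, 3)),
    "abnormal": Scenario("abnormal", (0, 1, 1, 1)),
    "critical": Scenario("critical", (0, 0, 0, 1)),
}


def map_labels(raw_scores, scenario: Scenario | str) -> np.ndarray:
    """Map raw scores 0-4 to scenario classes (4 folds into 3 first)."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    raw = np.asarray(raw_scores, dtype=int)
    if raw.size and (raw.min() < 0 or raw.max() > 4):
        raise ValueError("raw scores must be in 0..4")
    mapped = np.minimum(raw, 3)
    table = np.asarray(scenario.mapping, dtype=int)
    return table[mapped]


def loso_splits(subject_ids) -> list[tuple[list, object]]:
    """One fold per distinct subject: (sorted train subjects, test subject)."""
    subjects = sorted(set(subject_ids))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    return [([s for s in subjects if s != t], t) for t in subjects]


def smote_balance(X, y, seed: int = 0, k: int = 5):
    """Oversample every minority class to the majority count (1/k per class).

    New points are convex combinations ``x + u * (neighbor - x)`` of
    same-class nearest neighbours (u uniform in [0, 1]); original samples are
    preserved and come first.  A class with a single sample falls back to
    duplicate-then-interpolate (logged).  Already-balanced input is returned
    unchanged.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts == 0) or len(classes) == 0:
        raise ValueError("labels must be non-empty")
    target = counts.max()
    if np.all(counts == target):
        return X.copy(), y.copy()
    rng = np.random.default_rng(seed)
    new_X = [X]
    new_y = [y]
    for cls, count in zip(classes, counts):
        need = target - count
        if need == 0:
            continue
        Xc = X[y == cls]
        if count == 1:
            logger.warning("SMOTE fallback: class %r has a single sample; "
                           "duplicating it %d times", cls, need)
            new_X.append(np.repeat(Xc, need, axis=0))
            new_y.append(np.repeat(cls, need))
            continue
        k_eff = min(k, count - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # first neighbour is the point itself
        base = rng.integers(0, count, size=need)
        pick = rng.integers(1, k_eff + 1, size=need)
        u = rng.uniform(0.0, 1.0, size=need)[:, None]
        nbr = Xc[idx[base, pick]]
        new_X.append(Xc[base] + u * (nbr - Xc[base]))
        new_y.append(np.repeat(cls, need))
    return np.vstack(new_X), np.concatenate(new_y)


def aggregate_majority(segment_predictions) -> int:
    """Record prediction = modal segment class; ties go to the severer class."""
    preds = np.asarray(segment_predictions, dtype=int)
    if preds.size == 0:
        raise ValueError("need at least one segment prediction")
    classes, counts = np.unique(preds, return_counts=True)
    winners = classes[counts == counts.max()]
    return int(winners.max())


def _weighted_ovr_auc(y_true: np.ndarray, y_prob: np.ndarray,
                      classes: np.ndarray) -> float:
    aucs, weights = [], []
    for j, c in enumerate(classes):
        pos = y_true == c
        if pos.all() or not pos.any():
            continue
        aucs.append(roc_auc_score(pos, y_prob[:, j]))
        weights.append(pos.sum())
    if not aucs:
        return float("nan")
    return float(np.average(aucs, weights=weights))


def compute_metrics(y_true, y_pred, y_prob=None, classes=None) -> dict[str, float]:
    """Accuracy, weighted precision/recall/F1, ordinal RMSE and weighted AUC.

    RMSE treats class labels as ordinal indices.  AUC is the class-weighted
    one-vs-rest area (standard ROC AUC in the binary case) and requires
    `y_prob` with one column per class in `classes` order (defaults to the
    sorted union of true and predicted labels).
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, average="weighted", zero_division=0)
    out = {
        "accuracy": float(accuracy_score(y_true, y_pred)),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
    }
    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
        if len(y_prob) != len(y_true):
            raise ValueError("y_prob must match y_true in length")
        if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        if classes is None:
            classes = np.unique(np.concatenate([y_true, y_pred]))
        classes = np.asarray(classes)
        if y_prob.shape[1] != len(classes):
            raise ValueError("y_prob must have one column per class")
        out["auc"] = _weighted_ovr_auc(y_true, y_prob, classes)
    else:
        out["auc"] = float("nan")
    return out


def _fast_metric(metric: str, y_true: np.ndarray, y_pred: np.ndarray,
                 y_prob, classes: np.ndarray) -> float:
    """Closed-form metric evaluation without estimator-framework overhead.

    Agrees with :func:`compute_metrics` (which delegates to scikit-learn);
    used inside the bootstrap where the metric is evaluated thousands of
    times on small resamples.
    """
    if metric == "accuracy":
        return float(np.mean(y_true == y_pred))
    if metric == "rmse":
        return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if metric == "auc":
        if y_prob is None:
            return float("nan")
        aucs, weights = [], []
        for j, c in enumerate(classes):
            pos = y_true == c
            n_pos = int(pos.sum())
            n_neg = len(y_true) - n_pos
            if n_pos == 0 or n_neg == 0:
                continue
            ranks = spst.rankdata(y_prob[:, j])
            auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
            aucs.append(auc)
            weights.append(n_pos)
        return float(np.average(aucs, weights=weights)) if aucs else float("nan")
    # weighted precision / recall / f1 from the confusion matrix
    k = len(classes)
    ti = np.searchsorted(classes, y_true)
    pi = np.searchsorted(classes, y_pred)
    cm = np.bincount(ti * k + pi, minlength=k * k).reshape(k, k).astype(float)
    tp = np.diag(cm)
    support = cm.sum(axis=1)
    predicted = cm.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(predicted > 0, tp / predicted, 0.0)
        rec = np.where(support > 0, tp / support, 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    w = support / support.sum()
    return float({"precision": prec @ w, "recall": rec @ w, "f1": f1 @ w}[metric])


def bootstrap_ci(y_true, y_pred, y_prob, metric: str, B: int = 2000,
                 seed: int = 0, classes=None,
                 max_redraws: int = 100) -> tuple[float, float, float]:
    """Stratified bootstrap 95% CI of one metric.

    Records are resampled with replacement within each true-class stratum,
    preserving stratum sizes; bounds are the 2.5/97.5 percentiles over `B`
    replicates.  A replicate on which the metric is undefined (e.g. AUC with
    a single class after resampling) is redrawn, up to `max_redraws` times
    (counted and logged).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    point = compute_metrics(y_true, y_pred, y_prob, classes)[metric]
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    if y_prob is not None:
        y_prob = np.asarray(y_prob, dtype=float)
    strata = [np.flatnonzero(y_true == c) for c in np.unique(y_true)]
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    n_redraws = 0
    for b in range(B):
        for _ in range(max_redraws + 1):
            idx = np.concatenate([rng.choice(s, size=len(s), replace=True)
                                  for s in strata])
            prob = y_prob[idx] if y_prob is not None else None
            v = _fast_metric(metric, y_true[idx], y_pred[idx], prob, classes)
            if np.isfinite(v):
                break
            n_redraws += 1
        vals[b] = v
    if n_redraws:
        logger.info("bootstrap_ci(%s): %d undefined resamples redrawn", metric, n_redraws)
    lower, upper = np.percentile(vals, [2.5, 97.5])
    return float(point), float(lower), float(upper)


@dataclass(frozen=True)
class McNemarResult:
    b: int  # A correct, B wrong
    c: int  # A wrong, B correct
    statistic: float
    p_value: float
    significant: bool
    exact: bool


def mcnemar_compare(y_true, pred_a, pred_b, n_comparisons: int = 1) -> McNemarResult:
    """McNemar's paired test on discordant classifications.

    Exact two-sided binomial p-value when the discordant count b + c < 25,
    otherwise the chi-square statistic with continuity correction.
    Significance is judged at the Bonferroni-adjusted level
    ``0.05 / n_comparisons``.
    """
    y_true = np.asarray(y_true)
    a = np.asarray(pred_a)
    bb = np.asarray(pred_b)
    if not (len(y_true) == len(a) == len(bb)):
        raise ValueError("inputs must have equal length")
    a_right = a == y_true
    b_right = bb == y_true
    b_count = int(np.sum(a_right & ~b_right))
    c_count = int(np.sum(~a_right & b_right))
    n = b_count + c_count
    if n == 0:
        stat, p, exact = 0.0, 1.0, True
    elif n < 25:
        stat = float(min(b_count, c_count))
        p = float(min(1.0, 2.0 * spst.binom.cdf(min(b_count, c_count), n, 0.5)))
        exact = True
    else:
        stat = (abs(b_count - c_count) - 1) ** 2 / n
        p = float(spst.chi2.sf(stat, df=1))
        exact = False
    return McNemarResult(b=b_count, c=c_count, statistic=float(stat), p_value=p,
                         significant=p < 0.05 / n_comparisons, exact=exact)
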