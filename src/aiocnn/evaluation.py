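"""Classification metrics and evaluation protocols.

Binary metrics follow the textbook confusion-matrix formulas exactly:
accuracy = (TP+TN)/(TP+FP+TN+FN), precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 = 2*precision*recall/(precision+recall).  Ratios with a
zero denominator are *undefined* and reported as ``None``, never as 0.
ROC AUC is the Mann-Whitney statistic U/(n1*n0) with ties counted 1/2.

Multiclass tasks are reported one-vs-rest: per-class AUC from that class's
probability column, per-class "accuracy" meaning the recall of the class
(the fraction of its samples called correctly), categorical accuracy as
the fraction of argmax calls matching the truth, and class-frequency
weighted averages of every per-class metric.  For a binary task the
weighted average coincides with the overall metric.

The two evaluation protocols: stratified five-fold cross-validation with
80-20 splits (held-out predictions pooled across folds before computing
metrics) and external testing of a model trained on one cohort against an
independent cohort, accompanied by a dataset-consistency diagnostic — the
Pearson correlation of per-gene mean log2 expression between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .cnn import CNNClassifier, TrainConfig, predict_proba, train_model
from .errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    ShapeError,
    StratificationError,
    ValidationError,
)
from .expression import ExpressionMatrix, log2_transform

__all__ = [
    "ConfusionCounts",
    "BinaryMetrics",
    "MetricsReport",
    "CVPlan",
    "binary_metrics",
    "binary_report",
    "roc_auc",
    "one_vs_rest_report",
    "weighted_average",
    "stratified_kfold",
    "cross_validate",
    "external_test",
    "diagnose_consistency",
]


# ---------------------------------------------------------------------------
# confusion counts and binary metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_calls(cls, truth: np.ndarray, calls: np.ndarray) -> "ConfusionCounts":
        truth = np.asarray(truth).astype(int)
        calls = np.asarray(calls).astype(int)
        return cls(
            tp=int(np.sum((truth == 1) & (calls == 1))),
            fp=int(np.sum((truth == 0) & (calls == 1))),
            tn=int(np.sum((truth == 0) & (calls == 0))),
            fn=int(np.sum((truth == 1) & (calls == 0))),
        )


@dataclass(frozen=True)
class BinaryMetrics:
    """Accuracy/precision/recall/F1; ``None`` marks an undefined ratio."""

    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def binary_metrics(counts: ConfusionCounts) -> BinaryMetrics:
    """Evaluate the four confusion-matrix formulas exactly."""
    if counts.total == 0:
        raise ValidationError("cannot evaluate metrics on zero samples")
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    recall = _ratio(counts.tp, counts.tp + counts.fn)
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return BinaryMetrics(
        accuracy=(counts.tp + counts.tn) / counts.total,
        precision=precision,
        recall=recall,
        f1=f1,
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC as the normalized Mann-Whitney U with ties counted 1/2."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ShapeError("labels and scores must be equal-length vectors")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise DegenerateLabelsError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def weighted_average(values: Sequence[float], freqs: Sequence[float]) -> float:
    """Sum of class frequency times class-specific metric."""
    v = np.asarray(values, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if v.shape != f.shape:
        raise ShapeError("values and frequencies differ in length")
    if np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
        raise ValidationError("frequencies must be non-negative and sum to 1")
    return float(np.sum(f * v))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-class and weighted metrics for one evaluation.

    ``per_class`` maps class label -> {accuracy, auc, precision, recall,
    f1}; for multiclass reports the per-class accuracy is the recall of
    that class.  ``weighted`` holds the class-frequency weighted averages
    and ``overall`` the pooled quantities (binary metrics, or categorical
    accuracy for multiclass).
    """

    task: str                     # "binary" | "multiclass"
    n: int
    per_class: dict[int, dict[str, float | None]]
    weighted: dict[str, float | None]
    overall: dict[str, float | None]
    per_fold: list[dict] = field(default_factory=list)
    consistency_r: float | None = None  # cross-cohort diagnostic, if computed

    def to_frame(self) -> pd.DataFrame:
        rows = {f"class_{c}": m for c, m in self.per_class.items()}
        rows["weighted_average"] = self.weighted
        return pd.DataFrame(rows).T


def _class_frequencies(truth: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return np.array([(truth == c).mean() for c in classes])


def binary_report(truth: np.ndarray, probs: np.ndarray,
                  threshold: float = 0.5) -> MetricsReport:
    """Full binary report: per-class rows for 0/1 plus the weighted row."""
    truth = np.asarray(truth).astype(int)
    probs = np.asarray(probs, dtype=float)
    calls = (probs > threshold).astype(int)
    auc = roc_auc(truth, probs)
    per_class: dict[int, dict] = {}
    for c in (0, 1):
        t = (truth == c).astype(int)
        k = (calls == c).astype(int)
        m = binary_metrics(ConfusionCounts.from_calls(t, k))
        per_class[c] = {
            "accuracy": m.accuracy,
            "auc": auc if c == 1 else roc_auc(t, 1.0 - probs),
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
        }
    freqs = _class_frequencies(truth, np.array([0, 1]))
    weighted = {
        k: _weighted_or_none([per_class[0][k], per_class[1][k]], freqs)
        for k in ("accuracy", "auc", "precision", "recall", "f1")
    }
    m_all = binary_metrics(ConfusionCounts.from_calls(truth, calls))
    overall = {
        "accuracy": m_all.accuracy,
        "auc": auc,
        "precision": m_all.precision,
        "recall": m_all.recall,
        "f1": m_all.f1,
    }
    return MetricsReport(task="binary", n=truth.size, per_class=per_class,
                         weighted=weighted, overall=overall)


def _weighted_or_none(values, freqs):
    if any(v is None for v in values):
        return None
    return weighted_average(values, freqs)


def one_vs_rest_report(truth: np.ndarray, probs: np.ndarray) -> MetricsReport:
    """Multiclass report: per-class one-vs-rest metrics + weighted row.

    Calls come from the probability argmax (ties to the lowest index).
    Per-class accuracy is the recall of that class; categorical accuracy
    is the fraction of correct argmax calls.
    """
    truth = np.asarray(truth).astype(int)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != truth.size:
        raise ShapeError("probs must be (n_samples, n_classes)")
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1) > 1e-6):
        raise ValidationError("probability rows must lie on the simplex")
    k = probs.shape[1]
    classes = np.arange(k)
    present = np.unique(truth)
    if present.size < 2:
        raise DegenerateLabelsError("need >= 2 classes present")
    calls = np.argmax(probs, axis=1)
    per_class: dict[int, dict] = {}
    for c in classes:
        t = (truth == c).astype(int)
        cl = (calls == c).astype(int)
        m = binary_metrics(ConfusionCounts.from_calls(t, cl))
        auc = roc_auc(t, probs[:, c]) if 0 < t.sum() < t.size else None
        per_class[int(c)] = {
            "accuracy": m.recall,   # per-class accuracy == class recall
            "auc": auc,
            "precision": m.precision,
            "recall": m.recall,
            "f1": m.f1,
        }
    freqs = _class_frequencies(truth, classes)
    weighted = {
        key: _weighted_or_none([per_class[int(c)][key] for c in classes], freqs)
        for key in ("accuracy", "auc", "precision", "recall", "f1")
    }
    overall = {"accuracy": float((calls == truth).mean())}
    return MetricsReport(task="multiclass", n=truth.size, per_class=per_class,
                         weighted=weighted, overall=overall)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """Fold assignment per sample for stratified k-fold CV."""

    fold: np.ndarray  # (n,) int fold index per sample
    k: int
    stratified: bool
    seed: int

    def test_indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold == j)

    def train_indices(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.fold != j)


def stratified_kfold(labels: np.ndarray, k: int = 5, seed: int = 0) -> CVPlan:
    """Disjoint, exhaustive, label-stratified folds (sizes differ by <= 1)."""
    y = np.asarray(labels).astype(int)
    counts = pd.Series(y).value_counts()
    too_small = counts[counts < k]
    if len(too_small):
        raise StratificationError(
            f"class {too_small.index[0]} has {too_small.iloc[0]} members, "
            f"fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(y.size, dtype=int)
    for j, (_, test) in enumerate(skf.split(np.zeros((y.size, 1)), y)):
        fold[test] = j
    return CVPlan(fold=fold, k=k, stratified=True, seed=seed)


def cross_validate(
    aios: np.ndarray,
    labels: np.ndarray,
    builder: Callable[[int], CNNClassifier],
    cfg: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Stratified k-fold CV: train on (k-1)/k, predict the held-out fold.

    Held-out predictions are pooled over folds and the metrics computed
    once on the pooled set (per-fold sample counts are logged in
    ``per_fold``).  ``builder(seed)`` must return a fresh classifier.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(labels).astype(int)
    plan = stratified_kfold(y, k=k, seed=seed)
    n = y.size
    binary = builder(0).spec.n_classes == 2
    pooled = np.full(n, np.nan) if binary else None
    per_fold = []
    for j in range(k):
        tr, te = plan.train_indices(j), plan.test_indices(j)
        model = builder(seed + 1000 * (j + 1))
        fold_cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed + j})
        train_model(model, aios[tr], y[tr], fold_cfg)
        preds = predict_proba(model, aios[te], threshold=threshold)
        if binary:
            pooled[te] = preds.probs
        else:
            if pooled is None or pooled.ndim == 1:
                pooled = np.full((n, preds.probs.shape[1]), np.nan)
            pooled[te] = preds.probs
        per_fold.append({"fold": j, "n_train": int(tr.size),
                         "n_test": int(te.size)})
    assert not np.any(np.isnan(pooled)), "every sample predicted exactly once"
    report = (binary_report(y, pooled, threshold) if binary
              else one_vs_rest_report(y, pooled))
    report.per_fold = per_fold
    return report


def external_test(
    train_aios: np.ndarray,
    train_labels: np.ndarray,
    test_aios: np.ndarray,
    test_labels: np.ndarray,
    builder: Callable[[int], CNNClassifier],
    cfg: TrainConfig | None = None,
    train_gene_order: Sequence[str] | None = None,
    test_gene_order: Sequence[str] | None = None,
    train_expression: ExpressionMatrix | None = None,
    test_expression: ExpressionMatrix | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Train on the full labeled training cohort, evaluate an external one.

    If both cohorts' gene orders are supplied they must match exactly
    (the images are only comparable when every pixel means the same gene);
    a mismatch raises before any training starts.  When the raw
    expression matrices are supplied as well, the cross-cohort
    consistency diagnostic is computed alongside and attached to the
    report as ``consistency_r``.
    """
    if train_gene_order is not None and test_gene_order is not None:
        if list(train_gene_order) != list(test_gene_order):
            raise ValidationError(
                "training and testing cohorts use different gene orders"
            )
    cfg = cfg or TrainConfig()
    y_tr = np.asarray(train_labels).astype(int)
    y_te = np.asarray(test_labels).astype(int)
    model = builder(cfg.seed)
    train_model(model, train_aios, y_tr, cfg)
    preds = predict_proba(model, test_aios, threshold=threshold)
    if model.spec.n_classes == 2:
        report = binary_report(y_te, preds.probs, threshold)
    else:
        report = one_vs_rest_report(y_te, preds.probs)
    if train_expression is not None and test_expression is not None:
        report.consistency_r = diagnose_consistency(train_expression,
                                                    test_expression)
    return report


# ---------------------------------------------------------------------------
# dataset-shift diagnostic
# ---------------------------------------------------------------------------

def diagnose_consistency(mat_a: ExpressionMatrix,
                         mat_b: ExpressionMatrix) -> float:
    """Pearson r of per-gene mean log2 expression between two cohorts.

    A technical measure of cross-cohort replicability: matched cohorts
    score near 1; values around 0.8 flag dataset shift severe enough to
    degrade model transfer.  FPKM-scale inputs are log2(x+1)-transformed
    first; only shared genes enter.
    """
    a = mat_a if mat_a.scale == "log2" else log2_transform(mat_a)
    b = mat_b if mat_b.scale == "log2" else log2_transform(mat_b)
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared genes; need >= 3 for a correlation"
        )
    mean_a = a.subset_genes(shared).values.mean(axis=0)
    mean_b = b.subset_genes(shared).values.mean(axis=0)
    r, _ = stats.pearsonr(mean_a, mean_b)
    return float(r)
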