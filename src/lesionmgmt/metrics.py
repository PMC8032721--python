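"""Confusion matrices, class-wise metrics and one-vs-rest AUROC.

Per-class metrics follow the one-vs-rest convention: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP), with
zero-denominator cases returning 0 and a flag (so macro averages stay
defined — an empty predicted class yields precision 0, not NaN). Macro
averages are unweighted class means; overall accuracy is trace/total.
AUROC is the Mann-Whitney probability with half-credit for ties,
macro-averaged over classes with at least one positive and one negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


@dataclass
class ConfusionMatrix:
    """K x K count matrix, rows = true, columns = predicted; optionally a
    per-cell breakdown by a secondary label (e.g. diagnosis)."""

    counts: np.ndarray
    class_names: tuple[str, ...] | None = None
    breakdown: np.ndarray | None = None  # K x K x n_breakdown
    breakdown_names: tuple[str, ...] | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClasswiseMetrics:
    sensitivity: np.ndarray
    specificity: np.ndarray
    precision: np.ndarray
    auroc: np.ndarray | None
    overall_accuracy: float
    zero_denominator_flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def macro_sensitivity(self) -> float:
        return float(np.mean(self.sensitivity))

    @property
    def macro_specificity(self) -> float:
        return float(np.mean(self.specificity))

    @property
    def macro_precision(self) -> float:
        return float(np.mean(self.precision))

    @property
    def macro_auroc(self) -> float:
        if self.auroc is None:
            return float("nan")
        return float(np.nanmean(self.auroc))

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity.tolist(),
            "specificity": self.specificity.tolist(),
            "precision": self.precision.tolist(),
            "auroc": None if self.auroc is None else self.auroc.tolist(),
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "macro_precision": self.macro_precision,
            "macro_auroc": self.macro_auroc,
            "overall_accuracy": self.overall_accuracy,
        }


def confusion_matrix(
    true_labels: np.ndarray,
    pred_labels: np.ndarray,
    n_classes: int,
    class_names: tuple[str, ...] | None = None,
    breakdown_by: np.ndarray | None = None,
    breakdown_names: tuple[str, ...] | None = None,
) -> ConfusionMatrix:
    """Tally counts[i, j] = #{true = i, predicted = j}, with an optional
    per-cell breakdown by a secondary label vector (diagnosis, typically)."""
    t = np.asarray(true_labels, dtype=np.int64)
    p = np.asarray(pred_labels, dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError("true and predicted label vectors differ in length")
    for v in (t, p):
        if v.size and (v.min() < 0 or v.max() >= n_classes):
            raise ValueError("label index out of range")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (t, p), 1)
    breakdown = None
    if breakdown_by is not None:
        b = np.asarray(breakdown_by, dtype=np.int64)
        if b.shape != t.shape:
            raise ValueError("breakdown vector length mismatch")
        nb = b.max() + 1 if b.size else 0
        if breakdown_names is not None:
            nb = max(nb, len(breakdown_names))
        breakdown = np.zeros((n_classes, n_classes, nb), dtype=np.int64)
        np.add.at(breakdown, (t, p, b), 1)
    return ConfusionMatrix(counts, class_names, breakdown, breakdown_names)


def classwise_metrics(
    cm: ConfusionMatrix, auroc: np.ndarray | None = None
) -> ClasswiseMetrics:
    """One-vs-rest sensitivity/specificity/precision per class, macro means
    and overall accuracy, from a confusion matrix."""
    counts = np.asarray(cm.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fn = counts.sum(axis=1) - tp
    fp = counts.sum(axis=0) - tp
    tn = total - tp - fn - fp

    flags: dict[str, np.ndarray] = {}

    def safe_ratio(num: np.ndarray, den: np.ndarray, name: str) -> np.ndarray:
        zero = den == 0
        flags[name] = zero
        out = np.zeros_like(num, dtype=float)
        np.divide(num, den, out=out, where=~zero)
        return out

    return ClasswiseMetrics(
        sensitivity=safe_ratio(tp, tp + fn, "sensitivity"),
        specificity=safe_ratio(tn, tn + fp, "specificity"),
        precision=safe_ratio(tp, tp + fp, "precision"),
        auroc=auroc,
        overall_accuracy=float(np.trace(counts) / total),
        zero_denominator_flags=flags,
    )


def _binary_auroc(truth: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUROC with half-credit for ties (rank-sum form)."""
    pos = truth == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks handle ties with half credit
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc_one_vs_rest(true_labels: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Per-class one-vs-rest AUROC; NaN (flagged) for a class with no
    positives or no negatives. Macro AUROC is the mean of defined entries."""
    t = np.asarray(true_labels, dtype=np.int64)
    P = np.asarray(probs, dtype=float)
    if t.size != P.shape[0]:
        raise ValueError("label/probability length mismatch")
    if np.unique(t).size < 2:
        raise ValueError("AUROC undefined: single-class input")
    return np.array([_binary_auroc((t == k).astype(int), P[:, k]) for k in range(P.shape[1])])


def curve_points(
    true_binary: np.ndarray, scores: np.ndarray, kind: str = "roc"
) -> np.ndarray:
    """ROC (FPR, TPR) or PR (recall, precision) points from a threshold
    sweep over the unique scores, in decreasing-threshold order."""
    t = np.asarray(true_binary, dtype=np.int64)
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("non-finite scores")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("curve undefined: single-class truth")
    order = np.argsort(-s, kind="stable")
    s_sorted, t_sorted = s[order], t[order]
    tp = np.cumsum(t_sorted == 1)
    fp = np.cumsum(t_sorted == 0)
    last_of_tie = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp, fp = tp[last_of_tie], fp[last_of_tie]
    if kind == "roc":
        fpr = np.r_[0.0, fp / n_neg]
        tpr = np.r_[0.0, tp / n_pos]
        return np.column_stack([fpr, tpr])
    if kind == "pr":
        recall = tp / n_pos
        precision = tp / (tp + fp)
        return np.column_stack([recall, precision])
    raise ValueError(f"unknown curve kind {kind!r}")


def trapezoid_auc(points: np.ndarray) -> float:
    """Area under an (x, y) point list by the trapezoidal rule."""
    x, y = points[:, 0], points[:, 1]
    return float(np.trapezoid(y, x))
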