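"""Confusion-matrix metrics and threshold-free curve areas.

The positive class is ``is_hyper`` (label 1).  PR-AUC uses step-wise
(rectangular) integration over the distinct score thresholds, with
tied scores grouped — the conservative convention that avoids the
over-optimism of linear precision interpolation; when every score is
identical the curve is the single point (recall 1, precision =
prevalence) and the area equals the positive prevalence.  ROC-AUC is
integrated with the trapezoid rule over the tie-grouped ROC points,
which equals the pairwise concordance U-statistic (ties counted half)
exactly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "basic_rates",
    "pr_auc",
    "roc_auc",
    "score_report",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass
class MetricsReport:
    """Per-evaluation bundle of counts, rates and curve areas."""

    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    fpr: float
    pr_auc: float | None = None
    roc_auc: float | None = None
    degenerate: bool = False

    def to_dict(self):
        return {
            "tp": self.counts.tp, "fp": self.counts.fp,
            "tn": self.counts.tn, "fn": self.counts.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "fpr": self.fpr,
            "pr_auc": self.pr_auc, "roc_auc": self.roc_auc,
            "degenerate": self.degenerate,
        }


def confusion_counts(predictions, labels) -> ConfusionCounts:
    """Standard 2x2 counts with is_hyper (1) as the positive class."""
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels differ in length")
    if predictions.size == 0:
        raise ValueError("empty input")
    tp = int(np.sum((predictions == 1) & (labels == 1)))
    fp = int(np.sum((predictions == 1) & (labels == 0)))
    tn = int(np.sum((predictions == 0) & (labels == 0)))
    fn = int(np.sum((predictions == 0) & (labels == 1)))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def basic_rates(c: ConfusionCounts) -> tuple:
    """(accuracy, precision, recall, fpr); 0/0 denominators yield 0 and
    set a degenerate flag (returned as a 5th element)."""
    degenerate = False

    def _ratio(num, den):
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    accuracy = _ratio(c.tp + c.tn, c.total)
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    fpr = _ratio(c.fp, c.tn + c.fp)
    return accuracy, precision, recall, fpr, degenerate


def _sorted_groups(scores, labels):
    """Cumulative (tp, fp) after each distinct score, descending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(scores)):
        raise ValueError("non-finite scores")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # group tied scores
    boundaries = np.flatnonzero(np.diff(s)) + 1
    tp_cum = np.cumsum(y)
    fp_cum = np.cumsum(1 - y)
    idx = np.append(boundaries - 1, y.size - 1)
    return tp_cum[idx], fp_cum[idx], n_pos, n_neg


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve, step integration.

    ``scores`` are probabilities of the positive class; tied scores are
    grouped into one operating point.
    """
    tp, fp, n_pos, _ = _sorted_groups(scores, labels)
    recall = tp / n_pos
    precision = tp / np.maximum(tp + fp, 1)
    prev_recall = 0.0
    area = 0.0
    for r, p in zip(recall, precision):
        area += (r - prev_recall) * p
        prev_recall = r
    return float(area)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (trapezoid over tie-grouped points).

    Equals the concordance probability
    ``(#concordant + 0.5 * #tied) / (n_pos * n_neg)`` exactly.
    """
    tp, fp, n_pos, n_neg = _sorted_groups(scores, labels)
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    return float(np.trapezoid(tpr, fpr))


def score_report(predictions, labels, scores=None) -> MetricsReport:
    """Full metrics bundle for one evaluation pass.

    Curve areas are computed when ``scores`` is given and both classes
    are present, else left as None.
    """
    c = confusion_counts(predictions, labels)
    acc, prec, rec, fpr, degenerate = basic_rates(c)
    pr = roc = None
    if scores is not None:
        labels_arr = np.asarray(labels, dtype=int)
        if 0 < labels_arr.sum() < labels_arr.size:
            pr = pr_auc(scores, labels_arr)
            roc = roc_auc(scores, labels_arr)
    return MetricsReport(counts=c, accuracy=acc, precision=prec, recall=rec,
                         fpr=fpr, pr_auc=pr, roc_auc=roc,
                         degenerate=degenerate)
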