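"""Recall/precision/F-measure and the precision-decrement AUC.

The AUC here is the exact published trapezoid over consecutive
ascending-E-value-cutoff points,

    AUC = sum_k (recall_{k+1} + recall_k) * (precision_k - precision_{k+1}) / 2,

which integrates recall against the *decrement* of precision rather
than the classical ROC axes; with nested prediction sets (recall
non-decreasing, precision typically non-increasing) it lies in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "EvalCounts",
    "EvalCurve",
    "confusion_counts",
    "roc_curve",
    "auc",
]


@dataclass
class EvalCounts:
    tp: int
    fp: int
    fn: int
    recall: float
    precision: float
    f_measure: float
    recall_defined: bool = True
    precision_defined: bool = True


@dataclass
class EvalCurve:
    cutoffs: list
    points: list  # (recall_k, precision_k) per ascending cutoff
    counts: list = field(default_factory=list)
    auc: float = 0.0


def confusion_counts(predicted: set, truth: set) -> EvalCounts:
    """TP/FP/FN and the derived rates; undefined rates report 0 with a flag."""
    predicted = set(predicted)
    truth = set(truth)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    recall_defined = (tp + fn) > 0
    precision_defined = (tp + fp) > 0
    recall = tp / (tp + fn) if recall_defined else 0.0
    precision = tp / (tp + fp) if precision_defined else 0.0
    f = 2 * recall * precision / (recall + precision) if (recall + precision) > 0 else 0.0
    return EvalCounts(tp=tp, fp=fp, fn=fn, recall=recall, precision=precision,
                      f_measure=f, recall_defined=recall_defined,
                      precision_defined=precision_defined)


def roc_curve(read_evalues: dict, truth: set, cutoffs: list) -> EvalCurve:
    """One (recall, precision) point per ascending E-value cutoff.

    ``read_evalues`` maps read id -> best (minimum) E-value over all
    contigs the read was assigned to; point ``k`` uses the prediction set
    ``{r : E(r) <= cutoff_k}``, so prediction sets are nested.
    """
    cutoffs = list(cutoffs)
    if any(b <= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly ascending")
    curve = EvalCurve(cutoffs=cutoffs, points=[])
    for cut in cutoffs:
        predicted = {rid for rid, e in read_evalues.items() if e <= cut}
        counts = confusion_counts(predicted, truth)
        curve.points.append((counts.recall, counts.precision))
        curve.counts.append(counts)
    if len(curve.points) >= 2:
        curve.auc = auc(curve)
    return curve


def auc(curve: EvalCurve) -> float:
    """The published precision-decrement trapezoid sum, verbatim."""
    pts = curve.points
    if len(pts) < 2:
        raise ValueError("AUC needs at least 2 curve points")
    total = 0.0
    for k in range(len(pts) - 1):
        r_k, p_k = pts[k]
        r_k1, p_k1 = pts[k + 1]
        total += (r_k1 + r_k) * (p_k - p_k1) / 2.0
    return total
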