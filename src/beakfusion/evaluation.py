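"""Confusion matrices and classification metrics.

Per class ``c`` the one-vs-rest counts are TP (diagonal), FP (rest of the
column), FN (rest of the row) and TN (everything else), and the four
standard metrics are

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

with zero-denominator cases defined as 0 (a warning is logged).  The
aggregate row reports overall accuracy (trace/total) and unweighted (macro)
means of precision, recall and F1; on balanced test sets the macro and
support-weighted averages coincide.  The plain-text report mirrors the
per-species tables of the beak study, where the per-class Accuracy column
equals recall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from beakfusion.errors import DataError, LabelError

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """K x K counts; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    class_order: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        k = len(self.class_order)
        if c.shape != (k, k):
            raise DataError(f"counts shape {c.shape} does not match {k} classes")
        if (c < 0).any():
            raise DataError("confusion-matrix counts must be non-negative")
        self.counts = c

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_order, columns=self.class_order)


@dataclass
class ClassMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class MetricsReport:
    per_class: Mapping[str, ClassMetrics]
    aggregate: ClassMetrics  # accuracy = trace/total; others macro-averaged

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "class": "ALL",
                "accuracy": self.aggregate.accuracy,
                "precision": self.aggregate.precision,
                "recall": self.aggregate.recall,
                "f1": self.aggregate.f1,
            }
        ]
        for c, m in self.per_class.items():
            rows.append(
                {"class": c, "accuracy": m.accuracy, "precision": m.precision,
                 "recall": m.recall, "f1": m.f1}
            )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        """Per-species table; the Accuracy column is the class recall."""
        lines = [f"{'Species':<16}{'Accuracy':>10}{'Precision':>11}{'Recall':>9}{'F1':>9}"]
        lines.append(
            f"{'ALL':<16}{self.aggregate.accuracy:>9.2%}{self.aggregate.precision:>10.2%}"
            f"{self.aggregate.recall:>9.2%}{self.aggregate.f1:>9.2%}"
        )
        for c, m in self.per_class.items():
            lines.append(
                f"{c:<16}{m.recall:>9.2%}{m.precision:>10.2%}{m.recall:>9.2%}{m.f1:>9.2%}"
            )
        return "\n".join(lines)


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    """Count true-class x predicted-class occurrences."""
    if len(y_true) != len(y_pred):
        raise DataError("y_true and y_pred must have equal length")
    order = list(class_order)
    index = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index:
            raise LabelError(f"true label {t!r} not in class order {order}")
        if p not in index:
            raise LabelError(f"predicted label {p!r} not in class order {order}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=order)


def _safe_div(num: float, den: float, what: str, cls: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s of class %r; reporting 0", what, cls)
        return 0.0
    return num / den


def binary_metrics(tp: int, fn: int, fp: int, tn: int, cls: str = "") -> ClassMetrics:
    """The four metrics from raw one-vs-rest counts."""
    total = tp + tn + fp + fn
    acc = _safe_div(tp + tn, total, "accuracy", cls)
    prec = _safe_div(tp, tp + fp, "precision", cls)
    rec = _safe_div(tp, tp + fn, "recall", cls)
    f1 = _safe_div(2 * prec * rec, prec + rec, "F1", cls)
    return ClassMetrics(accuracy=acc, precision=prec, recall=rec, f1=f1)


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Per-class one-vs-rest metrics and the macro aggregate."""
    if cm.total == 0:
        raise DataError("cannot compute metrics of an empty confusion matrix")
    counts = cm.counts
    per_class: dict[str, ClassMetrics] = {}
    for i, c in enumerate(cm.class_order):
        tp = int(counts[i, i])
        fp = int(counts[:, i].sum() - tp)
        fn = int(counts[i, :].sum() - tp)
        tn = cm.total - tp - fp - fn
        per_class[c] = binary_metrics(tp, fn, fp, tn, cls=c)
    overall_acc = float(np.trace(counts)) / cm.total
    agg = ClassMetrics(
        accuracy=overall_acc,
        precision=float(np.mean([m.precision for m in per_class.values()])),
        recall=float(np.mean([m.recall for m in per_class.values()])),
        f1=float(np.mean([m.f1 for m in per_class.values()])),
    )
    return MetricsReport(per_class=per_class, aggregate=agg)
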