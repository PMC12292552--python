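"""Binary classification metrics for the speaker-independent protocol.

The positive class is PD throughout, so sensitivity is the recall of the
patient group and specificity the recall of the healthy controls.  Derived
metrics: accuracy, sensitivity, specificity, precision, and F1 as the
harmonic mean of sensitivity and precision.  Degenerate denominators return
0 with a warning flag rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

__all__ = ["ConfusionCounts", "MetricsReport", "confusion_from_predictions",
           "compute_metrics", "cumulative_confusion", "roc_curve_auc",
           "per_sentence_accuracy", "aggregate_reports"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float | None = None
    degenerate: bool = False  # a zero denominator was coerced to 0

    def as_dict(self) -> dict[str, float]:
        out = {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
               "specificity": self.specificity, "precision": self.precision,
               "f1": self.f1}
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Counts from integer labels (1 = PD positive class)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy / sensitivity / specificity / precision / F1 from counts."""
    if counts.total < 1:
        raise ValueError("confusion counts are empty")
    acc, d0 = _safe_div(counts.tp + counts.tn, counts.total)
    sn, d1 = _safe_div(counts.tp, counts.tp + counts.fn)
    sp, d2 = _safe_div(counts.tn, counts.tn + counts.fp)
    prec, d3 = _safe_div(counts.tp, counts.tp + counts.fp)
    f1, d4 = _safe_div(2.0 * sn * prec, sn + prec)
    return MetricsReport(accuracy=acc, sensitivity=sn, specificity=sp, precision=prec,
                         f1=f1, degenerate=any([d0, d1, d2, d3, d4]))


def cumulative_confusion(fold_counts: list[ConfusionCounts]) -> ConfusionCounts:
    """Elementwise sum of per-fold confusion matrices."""
    if not fold_counts:
        raise ValueError("need at least one fold result")
    total = ConfusionCounts()
    for c in fold_counts:
        total = total + c
    return total


def roc_curve_auc(scores: np.ndarray, labels: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (fpr, tpr) over the unique-score threshold sweep, plus AUC.

    The trapezoidal AUC equals the pairwise-concordance (Mann–Whitney)
    statistic.  Requires both classes present.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    return fpr, tpr, float(_skm.auc(fpr, tpr))


def per_sentence_accuracy(y_true, y_pred, sentence_ids) -> pd.DataFrame:
    """Accuracy within each sentence type, sorted descending."""
    frame = pd.DataFrame({"sentence_id": sentence_ids,
                          "correct": np.asarray(y_true) == np.asarray(y_pred)})
    table = (frame.groupby("sentence_id")["correct"].agg(["mean", "size"])
             .rename(columns={"mean": "accuracy", "size": "n"})
             .reset_index())
    return table.sort_values("accuracy", ascending=False, kind="stable").reset_index(drop=True)


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, tuple[float, float]]:
    """Per-metric mean ± sample (n−1) standard deviation across folds."""
    out: dict[str, tuple[float, float]] = {}
    keys = ["accuracy", "sensitivity", "specificity", "precision", "f1"]
    if all(r.auc is not None for r in reports):
        keys.append("auc")
    for key in keys:
        values = np.array([getattr(r, key) for r in reports], dtype=float)
        sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        out[key] = (float(values.mean()), sd)
    return out
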