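"""Confusion-matrix evaluation: per-class precision/recall/F1 and accuracy.

Multi-class metrics are computed one-vs-rest from the confusion matrix
(rows = true class, columns = predicted): for class c, TP = M[c,c],
FP = column sum minus TP, FN = row sum minus TP; precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 = 2PR/(P+R), accuracy = trace/total.  Undefined
ratios (zero denominators) are reported as 0 with a warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["MetricsReport", "confusion", "per_class_metrics"]


@dataclass
class MetricsReport:
    """Per-class metrics plus overall accuracy, with zero-division flags."""

    matrix: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    zero_division_flags: list[str] = field(default_factory=list)

    def to_frame(self, class_names=None) -> pd.DataFrame:
        k = len(self.precision)
        names = class_names if class_names is not None else [str(i) for i in range(k)]
        df = pd.DataFrame(
            {"class": list(names), "precision": self.precision,
             "recall": self.recall, "f1": self.f1}
        )
        df.loc[len(df)] = ["macro", self.macro_precision, self.macro_recall,
                           self.macro_f1]
        df.attrs["accuracy"] = self.accuracy
        return df


def confusion(labels, predictions, num_classes: int) -> np.ndarray:
    """K x K count matrix: entry (i, j) = #(true i, predicted j)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    for name, arr in (("labels", labels), ("predictions", predictions)):
        if len(arr) and (arr.min() < 0 or arr.max() >= num_classes):
            raise IndexError(f"{name} outside [0, {num_classes})")
    idx = labels * num_classes + predictions
    return np.bincount(idx, minlength=num_classes**2).reshape(num_classes,
                                                              num_classes)


def _safe_div(num: float, den: float, flags: list[str], what: str) -> float:
    if den == 0:
        flags.append(what)
        return 0.0
    return num / den


def per_class_metrics(matrix) -> MetricsReport:
    """One-vs-rest precision/recall/F1 per class plus overall accuracy."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {m.shape}")
    if np.any(m < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    k = m.shape[0]
    flags: list[str] = []
    tp = np.diag(m).astype(float)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    precision = np.array(
        [_safe_div(tp[c], tp[c] + fp[c], flags, f"precision[{c}]") for c in range(k)]
    )
    recall = np.array(
        [_safe_div(tp[c], tp[c] + fn[c], flags, f"recall[{c}]") for c in range(k)]
    )
    f1 = np.array(
        [_safe_div(2 * precision[c] * recall[c], precision[c] + recall[c],
                   flags, f"f1[{c}]") for c in range(k)]
    )
    total = m.sum()
    accuracy = _safe_div(float(tp.sum()), float(total), flags, "accuracy")
    return MetricsReport(
        matrix=m,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        zero_division_flags=flags,
    )
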