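"""Confusion matrices and the derived screening metrics.

Type II error is the false-negative rate FN/(TP+FN); type I error the
false-positive rate FP/(FP+TN).  Percentages are rounded to 2 decimals
for reporting; undefined rates (empty denominator) are reported as
``None`` rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import DataError

__all__ = ["ConfusionMatrix", "confusion_metrics", "confusion_from_predictions"]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DataError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
        )


def _pct(num: int, denom: int) -> float | None:
    if denom == 0:
        return None
    return round(100.0 * num / denom, 2)


def confusion_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity, specificity, type I/II errors and cell
    percentages, all in percent rounded to 2 decimals."""
    if cm.total == 0:
        raise DataError("empty confusion matrix")
    return {
        "counts": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "total": cm.total,
        "accuracy": _pct(cm.tp + cm.tn, cm.total),
        "sensitivity": _pct(cm.tp, cm.tp + cm.fn),
        "specificity": _pct(cm.tn, cm.tn + cm.fp),
        "type_I_error": _pct(cm.fp, cm.fp + cm.tn),
        "type_II_error": _pct(cm.fn, cm.tp + cm.fn),
        "cell_pct": {
            "tp": _pct(cm.tp, cm.total),
            "fp": _pct(cm.fp, cm.total),
            "fn": _pct(cm.fn, cm.total),
            "tn": _pct(cm.tn, cm.total),
        },
    }


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionMatrix:
    """Counts from +1/-1 truth and prediction arrays."""
    y_true = np.asarray(y_true, int)
    y_pred = np.asarray(y_pred, int)
    if y_true.shape != y_pred.shape:
        raise DataError("prediction/truth length mismatch")
    return ConfusionMatrix(
        tp=int(np.count_nonzero((y_true == 1) & (y_pred == 1))),
        fp=int(np.count_nonzero((y_true == -1) & (y_pred == 1))),
        fn=int(np.count_nonzero((y_true == 1) & (y_pred == -1))),
        tn=int(np.count_nonzero((y_true == -1) & (y_pred == -1))),
    )
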