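"""Evaluation: confusion matrices, macro metrics, BCS tolerance accuracies.

The confusion matrix follows the rows-are-actual, columns-are-predicted
convention.  Precision/recall/F1 are macro-averaged over classes with the
0/0 -> 0 convention (weighted-average recall would be algebraically identical
to accuracy, which the reported metrics are not, so macro is used).  All
percentages are rounded to 2 decimals.

Tolerance accuracy at +-0.25 admits the adjacent class on the 0.25-spaced
scale; at +-0.5 two class steps.  The comparison carries an absolute epsilon
of 1e-9 so 0.25-step float arithmetic is robust.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .bcs import BCS_VALUES, value_to_index

__all__ = [
    "EvalReport",
    "confusion_matrix",
    "classification_report",
    "tolerance_accuracy",
    "evaluate_predictions",
]

_TOL_EPS = 1e-9


@dataclass
class EvalReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    tolerance_accuracy_025: float
    tolerance_accuracy_05: float
    confusion: np.ndarray = field(repr=False)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "tolerance_accuracy_025": self.tolerance_accuracy_025,
            "tolerance_accuracy_05": self.tolerance_accuracy_05,
            "confusion": self.confusion.tolist(),
        }


def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """K×K counts; entry (a, p) counts samples with actual a, predicted p."""
    y_true = np.asarray(y_true, int).ravel()
    y_pred = np.asarray(y_pred, int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contains indices outside 0..{num_classes - 1}")
    return _sk_confusion_matrix(y_true, y_pred, labels=np.arange(num_classes))


def classification_report(cm: np.ndarray) -> dict[str, float]:
    """Accuracy and macro precision/recall/F1 from a confusion matrix.

    Values are percentages rounded to 2 decimals; per-class 0/0 divisions
    contribute 0 to the macro averages.
    """
    cm = np.asarray(cm, float)
    total = cm.sum()
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or total <= 0:
        raise ValueError("confusion matrix must be square with positive total")
    diag = np.diag(cm)
    col = cm.sum(axis=0)
    row = cm.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.where(col > 0, col, 1), 0.0)
        recall = np.where(row > 0, diag / np.where(row > 0, row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.where(pr > 0, pr, 1), 0.0)
    return {
        "accuracy": round(100.0 * diag.sum() / total, 2),
        "macro_precision": round(100.0 * precision.mean(), 2),
        "macro_recall": round(100.0 * recall.mean(), 2),
        "macro_f1": round(100.0 * f1.mean(), 2),
    }


def tolerance_accuracy(true_scores, pred_scores, tol: float) -> float:
    """Percentage of samples with ``|pred - true| <= tol`` on the BCS scale."""
    true_scores = np.asarray(true_scores, float).ravel()
    pred_scores = np.asarray(pred_scores, float).ravel()
    if true_scores.shape != pred_scores.shape:
        raise ValueError("score vectors must have equal length")
    if tol < 0:
        raise ValueError("tolerance must be nonnegative")
    for v in np.concatenate([true_scores, pred_scores]):
        value_to_index(v)  # raises for values off the scale
    hits = np.abs(pred_scores - true_scores) <= tol + _TOL_EPS
    return float(100.0 * hits.mean())


def evaluate_predictions(y_true_idx, y_pred_idx, num_classes: int = 5) -> EvalReport:
    """Full report from class-index predictions."""
    cm = confusion_matrix(y_true_idx, y_pred_idx, num_classes)
    metrics = classification_report(cm)
    scale = np.asarray(BCS_VALUES[:num_classes])
    true_scores = scale[np.asarray(y_true_idx, int)]
    pred_scores = scale[np.asarray(y_pred_idx, int)]
    return EvalReport(
        accuracy=metrics["accuracy"],
        macro_precision=metrics["macro_precision"],
        macro_recall=metrics["macro_recall"],
        macro_f1=metrics["macro_f1"],
        tolerance_accuracy_025=round(tolerance_accuracy(true_scores, pred_scores, 0.25), 2),
        tolerance_accuracy_05=round(tolerance_accuracy(true_scores, pred_scores, 0.5), 2),
        confusion=cm,
    )
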