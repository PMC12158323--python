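"""Binary-classification evaluation: confusion matrix, scores, ROC/AUC.

The positive class is DM (demineralized) throughout, so recall is the
sensitivity to demineralization — the quantity a screening tool cares about.
Undefined ratios (zero denominators) are reported as NaN and flagged, never
silently set to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["ConfusionMatrix", "ScoreReport", "ROCCurve", "confusion", "scores", "roc_auc"]

_VALID = {"ND", "DM"}


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with DM as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class ScoreReport:
    """The six standard scores; NaN marks an undefined ratio."""

    accuracy: float
    f1: float
    recall: float
    specificity: float
    precision: float
    npv: float
    undefined: tuple = ()

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy, "f1": self.f1, "recall": self.recall,
            "specificity": self.specificity, "precision": self.precision,
            "npv": self.npv, "undefined": list(self.undefined),
        }


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def confusion(labels_true: Sequence[str], labels_pred: Sequence[str]) -> ConfusionMatrix:
    """Confusion matrix from ND/DM label sequences (DM positive)."""
    if len(labels_true) != len(labels_pred):
        raise ValueError("true and predicted label sequences differ in length")
    if len(labels_true) == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    bad = (set(labels_true) | set(labels_pred)) - _VALID
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    tp = fn = tn = fp = 0
    for t, p in zip(labels_true, labels_pred):
        if t == "DM":
            tp += p == "DM"
            fn += p == "ND"
        else:
            tn += p == "ND"
            fp += p == "DM"
    return ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp)


def _ratio(num: float, den: float, name: str, undefined: List[str]) -> float:
    if den == 0:
        undefined.append(name)
        return math.nan
    return num / den


def scores(cm: ConfusionMatrix) -> ScoreReport:
    """Accuracy, F1, recall, specificity, precision and NPV from counts."""
    und: List[str] = []
    accuracy = (cm.tp + cm.tn) / cm.total
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", und)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", und)
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", und)
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv", und)
    if math.isnan(precision) or math.isnan(recall) or (precision + recall) == 0:
        und.append("f1")
        f1 = math.nan
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return ScoreReport(accuracy=accuracy, f1=f1, recall=recall,
                       specificity=specificity, precision=precision, npv=npv,
                       undefined=tuple(und))


def roc_auc(scores_pred: Sequence[float], labels_true: Sequence[str]) -> ROCCurve:
    """ROC by threshold sweep over the unique scores, AUC by trapezoidal rule.

    Equal scores are grouped into a single threshold step, which makes the
    trapezoid AUC identical to the Mann-Whitney pair-counting statistic with
    ties counted one half.
    """
    if len(scores_pred) != len(labels_true):
        raise ValueError("scores and labels differ in length")
    y = np.array([{"ND": 0, "DM": 1}[l] for l in labels_true])
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    s = np.asarray(scores_pred, dtype=float)
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)
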