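"""Evaluation metrics for glaucoma screening.

Glaucoma is the positive class throughout: sensitivity is the true-positive
rate on glaucomatous images, specificity the true-negative rate on normal
images. Ratios with a zero denominator are reported as NaN ("undefined")
with a warning, never silently as 0.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionMatrix:
    """Binary confusion counts; fp are normal images called glaucomatous,
    fn glaucomatous images called normal."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])


@dataclass
class MetricsReport:
    """Scalar metrics plus the ROC curve and per-class Dice overlap."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float
    roc_points: list
    dice_disc: float
    dice_cup: float
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_points"] = [[float(a), float(b)] for a, b in self.roc_points]
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def confusion(labels, predictions) -> ConfusionMatrix:
    """Confusion counts with glaucoma (1) as the positive class."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if labels.size == 0:
        raise ValueError("labels must be non-empty")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValueError("labels and predictions must be binary (0/1)")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def scalar_metrics(cm: ConfusionMatrix) -> tuple[float, float, float, float, float]:
    """(accuracy, sensitivity, specificity, precision, f1)."""
    accuracy = _ratio(cm.tp + cm.tn, cm.total, "accuracy")
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        warnings.warn("f1 is undefined; reporting NaN", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return accuracy, sensitivity, specificity, precision, f1


def roc_auc(labels, scores) -> tuple[list, float]:
    """ROC points over all score thresholds and the trapezoidal AUC.

    The AUC equals the concordance probability that a random positive
    outranks a random negative, ties counted one half.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.size != scores.size or labels.size == 0:
        raise ValueError("labels and scores must be non-empty and equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(labels, scores, pos_label=1)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))


def dice(seg_map, mask, class_id: int) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of one class; 1 when both empty."""
    seg_map = np.asarray(seg_map)
    mask = np.asarray(mask)
    if seg_map.shape != mask.shape:
        raise ValueError("seg_map and mask must have the same shape")
    a = seg_map == class_id
    b = mask == class_id
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
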