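"""Evaluation mathematics for the guidance models.

Accuracy = (TP + TN) / (TP + TN + FP + FN);
MAPE(%)  = (100 / n) * sum |Y_i - X_i| / Y_i   (Y_i ground truth, um);
MAE      = (1 / n)  * sum |Y_i - X_i|          (um);
fold aggregation reports mean +- standard error (sample SD / sqrt(n_folds)).
Percentages are reported on the 0-100 scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix", "RegressionResult", "FoldSummary", "RocResult",
    "accuracy", "mape", "mae", "roc_auc", "aggregate_mean_se",
    "confusion_from_predictions",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts. For multi-class bookkeeping use
    :func:`confusion_from_predictions`, which returns a K x K grid."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class RegressionResult:
    """Paired ground-truth / predicted needle-to-dura distances in um."""

    y_true: tuple
    y_pred: tuple

    def __post_init__(self):
        if len(self.y_true) != len(self.y_pred):
            raise ValueError("y_true and y_pred must have equal length")
        if len(self.y_true) < 1:
            raise ValueError("need at least one pair")

    @property
    def mape(self) -> float:
        return mape(self)

    @property
    def mae(self) -> float:
        return mae(self)


@dataclass(frozen=True)
class FoldSummary:
    """Per-fold metric values with their mean and standard error."""

    values: tuple
    mean: float
    se: float
    single_fold: bool = False


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: tuple
    tpr: tuple
    thresholds: tuple


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified frames, (TP+TN)/total."""
    if cm.total < 1:
        raise ValueError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def confusion_from_predictions(y_true, y_pred, n_classes: Optional[int] = None):
    """K x K count grid; rows are truth, columns prediction."""
    labels = None if n_classes is None else list(range(n_classes))
    return _sk_confusion(y_true, y_pred, labels=labels)


def mape(result: RegressionResult) -> float:
    """Mean absolute percentage error on the 0-100 scale."""
    y = np.asarray(result.y_true, dtype=float)
    x = np.asarray(result.y_pred, dtype=float)
    if np.any(y <= 0):
        raise ValueError(
            "MAPE requires strictly positive ground-truth distances")
    return float(100.0 * np.mean(np.abs(y - x) / y))


def mae(result: RegressionResult) -> float:
    """Mean absolute error in the same units as the distances (um)."""
    y = np.asarray(result.y_true, dtype=float)
    x = np.asarray(result.y_pred, dtype=float)
    return float(np.mean(np.abs(y - x)))


def roc_auc(scores: Sequence[float], truths: Sequence[int]) -> RocResult:
    """ROC curve and AUC with class 1 (the deeper tissue) as positive.

    AUC equals the probability that a random positive outscores a random
    negative, counting ties as one half (the Mann-Whitney statistic).
    """
    truths = np.asarray(truths, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if truths.min() == truths.max():
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(truths, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, fpr=tuple(fpr), tpr=tuple(tpr),
                     thresholds=tuple(thr))


def aggregate_mean_se(values: Sequence[float]) -> FoldSummary:
    """Mean and standard error (sample SD / sqrt(n)) over fold metrics.

    A single fold has no spread estimate; its SE is reported as 0 and the
    summary flagged ``single_fold``.
    """
    vals = tuple(float(v) for v in values)
    if len(vals) == 0:
        raise ValueError("no fold values to aggregate")
    arr = np.asarray(vals)
    if len(vals) == 1:
        return FoldSummary(values=vals, mean=float(arr[0]), se=0.0,
                           single_fold=True)
    se = float(arr.std(ddof=1) / np.sqrt(len(vals)))
    return FoldSummary(values=vals, mean=float(arr.mean()), se=se)
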