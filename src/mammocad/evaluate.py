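"""Confusion-matrix metrics, ROC curves and the area under the curve.

Accuracy, sensitivity and specificity follow the standard definitions

    AC = (TP + TN) / (TP + FP + TN + FN)
    SE = TP / (TP + FN)          SP = TN / (FP + TN)

and are reported as percentages on the 0-100 scale, as is the area under
the ROC curve (AUOC).  A score at or above the threshold counts as a
positive prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["ConfusionCounts", "RunMetrics", "UndefinedMetricError",
           "confusion", "accuracy", "sensitivity_specificity", "roc_auoc",
           "run_metrics"]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator class is empty."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class RunMetrics:
    """One run's performance, all on the 0-100 percentage scale."""

    AC: float
    SE: float
    SP: float
    AUOC: float

    def __post_init__(self) -> None:
        for name in ("AC", "SE", "SP", "AUOC"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")


def _check(labels, scores):
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")
    return y.astype(int), s


def confusion(labels: Sequence[int], scores: Sequence[float],
              threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN with score >= threshold meaning predicted positive."""
    y, s = _check(labels, scores)
    pred = s >= threshold
    return ConfusionCounts(TP=int(np.sum(pred & (y == 1))),
                           TN=int(np.sum(~pred & (y == 0))),
                           FP=int(np.sum(pred & (y == 0))),
                           FN=int(np.sum(~pred & (y == 1))))


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero cases")
    return 100.0 * (c.TP + c.TN) / c.total


def sensitivity_specificity(c: ConfusionCounts) -> Tuple[float, float]:
    if c.TP + c.FN == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive cases")
    if c.TN + c.FP == 0:
        raise UndefinedMetricError("specificity undefined: no negative cases")
    return 100.0 * c.TP / (c.TP + c.FN), 100.0 * c.TN / (c.FP + c.TN)


def roc_auoc(labels: Sequence[int], scores: Sequence[float]
             ) -> Tuple[np.ndarray, float]:
    """ROC curve (1-SP on x, SE on y) and its area on the 0-100 scale.

    The threshold sweeps the distinct score values (equal scores collapse
    into one step); the area is trapezoidal, which makes it equal to the
    Mann-Whitney pair-counting statistic.
    """
    y, s = _check(labels, scores)
    if np.unique(y).size < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    area = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), 100.0 * area


def run_metrics(labels: Sequence[int], scores: Sequence[float],
                threshold: float = 0.5) -> RunMetrics:
    """AC/SE/SP at the given threshold plus the threshold-free AUOC.

    The 0.5 default decision threshold is an assumption of the reporting
    convention, recorded here once.
    """
    c = confusion(labels, scores, threshold)
    se, sp = sensitivity_specificity(c)
    _, auoc = roc_auoc(labels, scores)
    return RunMetrics(AC=accuracy(c), SE=se, SP=sp, AUOC=auoc)
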