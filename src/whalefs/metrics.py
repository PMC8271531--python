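"""Binary-classification evaluation: confusion matrix, the four standard
rates, and ROC/AUC.

Conventions
-----------
* TP/FP/FN/TN follow the usual definitions (positive = the configured
  positive label).
* accuracy = (TP+TN)/total, precision = TP/(TP+FP),
  recall = sensitivity = TP/(TP+FN), specificity = TN/(TN+FP).
* A zero denominator raises :class:`UndefinedMetricError` — a degenerate
  evaluation should be visible, not silently 0.
* Counts are exact integers; ``percent`` rounds half-up only for display.
* Multiclass label vectors are binarized (default rule: label > 0 is
  positive) before any of these metrics, via :func:`binarize_labels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Callable, Sequence

import numpy as np

from .exceptions import DimensionMismatchError, UndefinedMetricError

__all__ = [
    "ConfusionMatrix",
    "ROCCurve",
    "confusion",
    "accuracy",
    "precision",
    "recall",
    "sensitivity",
    "specificity",
    "roc_curve",
    "binarize_labels",
    "percent",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts of a binary classification outcome."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ROCCurve:
    """An ROC curve: (FPR, TPR) points from (0,0) to (1,1), plus its AUC."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def binarize_labels(
    y: Sequence, positive_if: Callable = lambda v: v > 0
) -> np.ndarray:
    """Map a (possibly multiclass) label vector to {0, 1}.

    The default rule treats any label greater than zero as positive, which
    collapses 0–4 severity codes onto presence/absence.
    """
    return np.fromiter((1 if positive_if(v) else 0 for v in y), dtype=int)


def confusion(y_true: Sequence, y_pred: Sequence, positive_label) -> ConfusionMatrix:
    """Count the four expected-vs-predicted combinations."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise DimensionMismatchError(
            f"y_true and y_pred must be equal-length and non-empty "
            f"({y_true.shape} vs {y_pred.shape})"
        )
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


def _ratio(num: int, denom: int, what: str) -> float:
    if denom == 0:
        raise UndefinedMetricError(f"{what} is undefined: zero denominator")
    return num / denom


def accuracy(m: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    return _ratio(m.tp + m.tn, m.total, "accuracy")


def precision(m: ConfusionMatrix) -> float:
    """TP / (TP + FP)."""
    return _ratio(m.tp, m.tp + m.fp, "precision")


def recall(m: ConfusionMatrix) -> float:
    """TP / (TP + FN)."""
    return _ratio(m.tp, m.tp + m.fn, "recall")


def sensitivity(m: ConfusionMatrix) -> float:
    """TP / (TP + FN) — identical to recall by definition."""
    return recall(m)


def specificity(m: ConfusionMatrix) -> float:
    """TN / (TN + FP)."""
    return _ratio(m.tn, m.tn + m.fp, "specificity")


def percent(value: float, decimals: int = 2) -> float:
    """Display helper: value·100 rounded half-up to ``decimals`` places."""
    q = Decimal(10) ** -decimals
    return float(Decimal(value * 100).quantize(q, rounding=ROUND_HALF_UP))


def roc_curve(scores: Sequence[float], y_true: Sequence, positive_label) -> ROCCurve:
    """ROC curve from positive-class scores by descending-threshold sweep.

    Tied scores are grouped into a single threshold step; the AUC is the
    trapezoidal area, which equals the Mann–Whitney probability that a
    random positive outscores a random negative (ties counted half).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y_true)
    if scores.shape != y.shape or scores.size == 0:
        raise DimensionMismatchError("scores and y_true must be equal-length")
    pos = (y == positive_label).astype(int)
    n_pos = int(pos.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError(
            "ROC needs at least one positive and one negative instance"
        )
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    p = pos[order]
    # indices where a threshold group (run of tied scores) ends
    distinct = np.nonzero(np.diff(s))[0]
    ends = np.r_[distinct, len(s) - 1]
    tp_cum = np.cumsum(p)[ends]
    fp_cum = np.cumsum(1 - p)[ends]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, auc=auc)
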