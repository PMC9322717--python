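"""Confusion-count metrics, mask-overlap scoring, and the tracked loss.

Accuracy, precision and specificity follow the usual binary-classification
definitions.  Empty denominators raise typed errors rather than returning 0
so a degenerate evaluation can never silently pass.  The per-epoch training
loss is ``1 - mean(best similarity to the true class)`` — an artifact
definition chosen for this package, monotone in how well each sample
matches its own class's references.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, SchemaError, UndefinedMetricError
from .lvq import ClassificationResult

__all__ = [
    "ConfusionCounts",
    "EvalReport",
    "accuracy",
    "precision",
    "specificity",
    "dice",
    "epoch_loss",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise SchemaError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, positive) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        if yt.shape != yp.shape:
            raise SchemaError(f"label shapes differ: {yt.shape} vs {yp.shape}")
        pos_t = yt == positive
        pos_p = yp == positive
        return cls(
            tp=int(np.sum(pos_t & pos_p)),
            fp=int(np.sum(~pos_t & pos_p)),
            tn=int(np.sum(~pos_t & ~pos_p)),
            fn=int(np.sum(pos_t & ~pos_p)),
        )


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if c.total == 0:
        raise DegenerateInputError("accuracy of zero predictions is undefined")
    return (c.tp + c.tn) / c.total


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP)."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return c.tp / (c.tp + c.fp)


def specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP) — the true-negative rate."""
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative ground truth")
    return c.tn / (c.tn + c.fp)


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    a = np.asarray(pred) > 0
    b = np.asarray(truth) > 0
    if a.shape != b.shape:
        raise SchemaError(f"mask shapes differ: {a.shape} vs {b.shape}")
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def epoch_loss(results: list[ClassificationResult], labels) -> float:
    """Mean of ``1 - S_correct`` where ``S_correct`` is each sample's best
    similarity to its true class."""
    labels = list(labels)
    if len(results) == 0 or len(results) != len(labels):
        raise SchemaError("need one label per classification result")
    losses = []
    for res, true in zip(results, labels):
        if str(true) not in res.per_class:
            raise SchemaError(f"true class {true!r} absent from result classes")
        losses.append(1.0 - res.per_class[str(true)])
    return float(np.mean(losses))


@dataclass
class EvalReport:
    accuracy: float
    precision: float | None = None
    specificity: float | None = None
    dice: float | None = None
    loss_per_epoch: list[float] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "accuracy": self.accuracy,
                "precision": self.precision,
                "specificity": self.specificity,
                "dice": self.dice,
                "loss_per_epoch": self.loss_per_epoch,
            },
            indent=2,
        )
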