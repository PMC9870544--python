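"""Multiclass evaluation: confusion matrix, per-class P/R/F1, macro averages.

Sentiment evaluation is 3-class (positive/neutral/negative); emotion
evaluation is 9-class (the 8 categories plus neutral).  The overall numbers
are macro averages — unweighted arithmetic means of the per-class metrics —
plus plain accuracy (trace over total).  Display rounding is half-up to two
decimals; full precision is kept internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "round_half_up",
    "per_class_metrics",
    "macro_average",
    "accuracy",
    "evaluate_predictions",
    "SENTIMENT_CLASSES",
    "EMOTION_CLASSES",
]

SENTIMENT_CLASSES = ("positive", "neutral", "negative")
EMOTION_CLASSES = (
    "good",
    "joy",
    "surprise",
    "anticipate",
    "neutral",
    "disgust",
    "fear",
    "anger",
    "sadness",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (display convention), e.g. 0.005 -> 0.01."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square gold-by-predicted count matrix over an ordered class list."""

    labels: tuple[str, ...]
    counts: np.ndarray  # rows = gold, cols = predicted

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix must be square over labels")
        if (c < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(
        cls,
        gold: Sequence[str],
        predicted: Sequence[str],
        labels: Sequence[str] | None = None,
    ) -> "ConfusionMatrix":
        if len(gold) != len(predicted):
            raise ValueError("gold and predicted must have equal length")
        if labels is None:
            labels = sorted(set(gold) | set(predicted))
        idx = {lab: i for i, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for g, p in zip(gold, predicted):
            counts[idx[g], idx[p]] += 1
        return cls(labels=tuple(labels), counts=counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class MetricsReport:
    """Per-class precision/recall/F1 plus accuracy and macro averages."""

    labels: tuple[str, ...]
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float

    def summary(self, ndigits: int = 2) -> pd.DataFrame:
        """Rendered per-class + macro table, rounded half-up for display."""
        rows = [
            {
                "class": lab,
                "precision": round_half_up(self.precision[lab], ndigits),
                "recall": round_half_up(self.recall[lab], ndigits),
                "f1": round_half_up(self.f1[lab], ndigits),
            }
            for lab in self.labels
        ]
        rows.append(
            {
                "class": "macro average",
                "precision": round_half_up(self.macro_precision, ndigits),
                "recall": round_half_up(self.macro_recall, ndigits),
                "f1": round_half_up(self.macro_f1, ndigits),
            }
        )
        return pd.DataFrame(rows).set_index("class")

    def as_dict(self) -> dict:
        return {
            "per_class": {
                lab: {
                    "precision": self.precision[lab],
                    "recall": self.recall[lab],
                    "f1": self.f1[lab],
                }
                for lab in self.labels
            },
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
        }


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of posts on the diagonal (correctly labeled)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def macro_average(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean of per-class metric values."""
    values = list(values)
    if not values:
        raise ValueError("macro average of an empty list")
    return float(np.mean(values))


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall and F1 per class, with macro averages and accuracy.

    Classes with a zero denominator (no predictions, or no gold instances)
    score 0 for the affected metric, with a warning.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.astype(float)
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    precision, recall, f1 = {}, {}, {}
    for i, lab in enumerate(cm.labels):
        if tp[i] + fp[i] == 0:
            warnings.warn(f"class {lab!r} never predicted; precision set to 0", stacklevel=2)
            p = 0.0
        else:
            p = tp[i] / (tp[i] + fp[i])
        if tp[i] + fn[i] == 0:
            warnings.warn(f"class {lab!r} has no gold instances; recall set to 0", stacklevel=2)
            r = 0.0
        else:
            r = tp[i] / (tp[i] + fn[i])
        precision[lab] = float(p)
        recall[lab] = float(r)
        f1[lab] = float(2 * p * r / (p + r)) if p + r > 0 else 0.0
    return MetricsReport(
        labels=cm.labels,
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=accuracy(cm),
        macro_precision=macro_average(list(precision.values())),
        macro_recall=macro_average(list(recall.values())),
        macro_f1=macro_average(list(f1.values())),
    )


def evaluate_predictions(
    gold: Sequence[str],
    predicted: Sequence[str],
    labels: Sequence[str] | None = None,
) -> MetricsReport:
    """Convenience wrapper: labels in, MetricsReport out."""
    return per_class_metrics(ConfusionMatrix.from_labels(gold, predicted, labels))
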