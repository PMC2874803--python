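"""Confusion matrices and the five standard binary-classification metrics.

Given counts of true/false positives and negatives:

    specificity = TN / (TN + FP)        recall    = TP / (TP + FN)
    precision   = TP / (TP + FP)        accuracy  = (TP + TN) / total
    F1          = 2 * precision * recall / (precision + recall)

An undefined denominator yields 0 with an explicit flag rather than an
exception, so batch evaluation never aborts.  For an imbalanced dataset the
practical baseline for F1 is the positive-class frequency (a predictor that
calls everything hot attains precision = frequency and recall = 1, hence F1
near that frequency) — a useful model must beat it.
"""

from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "metrics",
    "baseline_f1",
    "round_half_up",
]


def round_half_up(value: float, digits: int = 2) -> float:
    """Decimal half-up rounding (0.005 -> 0.01), as used for reported tables."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of a binary hot/non-hot prediction against truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The matrix with positive/negative labels exchanged."""
        return ConfusionMatrix(tp=self.tn, tn=self.tp, fp=self.fn, fn=self.fp)


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """The five metrics plus flags naming any undefined (0-reported) ones."""

    specificity: float
    recall: float
    precision: float
    accuracy: float
    f1: float
    undefined: tuple[str, ...] = ()

    def rounded(self, digits: int = 2) -> dict[str, float]:
        return {
            name: round_half_up(getattr(self, name), digits)
            for name in ("specificity", "recall", "precision", "accuracy", "f1")
        }


def _safe_div(num: float, den: float, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Compute the five metrics from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    undefined: list[str] = []
    specificity = _safe_div(cm.tn, cm.tn + cm.fp, "specificity", undefined)
    recall = _safe_div(cm.tp, cm.tp + cm.fn, "recall", undefined)
    precision = _safe_div(cm.tp, cm.tp + cm.fp, "precision", undefined)
    accuracy = (cm.tp + cm.tn) / cm.total
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1", undefined)
    return MetricsReport(
        specificity=specificity,
        recall=recall,
        precision=precision,
        accuracy=accuracy,
        f1=f1,
        undefined=tuple(undefined),
    )


def baseline_f1(n_pos: int, n_total: int) -> float:
    """Random-predictor F1 baseline: the positive-class frequency."""
    if n_pos <= 0 or n_total <= 0:
        raise ValueError("counts must be positive")
    if n_pos > n_total:
        raise ValueError(f"n_pos={n_pos} exceeds n_total={n_total}")
    return n_pos / n_total
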