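"""Segmentation evaluation metrics for binary masks and mask stacks.

Implements the conformity / Jaccard / Dice family together with the
sensitivity-sensibility pair and three pixel-count error measures that are
customary in rodent-brain segmentation studies.  All similarity metrics are
reported as percentages; undefined cases (no true positives, empty gold mask)
surface as NaN rather than being silently mapped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "similarity_metrics",
    "error_metrics",
    "evaluate_masks",
    "aggregate_counts",
    "evaluate_stack",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixelwise confusion counts between a predicted and a gold mask."""

    tp: int
    fp: int
    fn: int

    @property
    def n_pred(self) -> int:
        """Pixel count of the predicted mask (Ns)."""
        return self.tp + self.fp

    @property
    def n_gold(self) -> int:
        """Pixel count of the gold-standard mask (Ng)."""
        return self.tp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    """Full metric suite for one mask comparison.

    Similarity metrics (conformity, jaccard, dice, sensitivity, sensibility)
    are percentages.  ``delta_n`` and ``delta_f`` are pixel counts and
    ``error_ratio`` is a percentage of the gold pixel count.

    Note on ``sensibility``: it is computed as ``(1 - FP/(TP+FN)) * 100``,
    i.e. the false-positive count is normalised by the *gold* mask size, not
    by the true-negative count as a textbook specificity would be.  This is
    deliberate; it measures over-segmentation relative to the object size and
    can be negative when FP exceeds the gold area.
    """

    conformity: float
    jaccard: float
    dice: float
    sensitivity: float
    sensibility: float
    delta_n: int
    delta_f: int
    error_ratio: float


def confusion_counts(pred: np.ndarray, gold: np.ndarray) -> ConfusionCounts:
    """Count TP/FP/FN pixels between two equally shaped binary masks."""
    pred = np.asarray(pred)
    gold = np.asarray(gold)
    if pred.shape != gold.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gold.shape}")
    p = pred.astype(bool)
    g = gold.astype(bool)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    return ConfusionCounts(tp, fp, fn)


def similarity_metrics(c: ConfusionCounts) -> tuple[float, float, float, float, float]:
    """Return (conformity, jaccard, dice, sensitivity, sensibility) in percent.

    Conformity is undefined (NaN) when there are no true positives; the other
    four are undefined only when all three counts vanish.
    """
    tp, fp, fn = float(c.tp), float(c.fp), float(c.fn)
    total = tp + fp + fn
    if total == 0.0:
        # both masks empty: perfect but degenerate agreement
        return float("nan"), 100.0, 100.0, 100.0, 100.0
    conformity = (1.0 - (fp + fn) / tp) * 100.0 if tp > 0 else float("nan")
    jaccard = tp / (tp + fn + fp) * 100.0
    dice = 2.0 * tp / (2.0 * tp + fn + fp) * 100.0
    gold = tp + fn
    sensitivity = tp / gold * 100.0 if gold > 0 else float("nan")
    sensibility = (1.0 - fp / gold) * 100.0 if gold > 0 else float("nan")
    return conformity, jaccard, dice, sensitivity, sensibility


def error_metrics(c: ConfusionCounts) -> tuple[int, int, float]:
    """Return (delta_n, delta_f, error_ratio%).

    delta_n = |Ns - Ng|, delta_f = FP + FN, error_ratio = delta_f / Ng * 100.
    """
    delta_n = abs(c.n_pred - c.n_gold)
    delta_f = c.fp + c.fn
    error_ratio = delta_f / c.n_gold * 100.0 if c.n_gold > 0 else float("nan")
    return delta_n, delta_f, error_ratio


def report_from_counts(c: ConfusionCounts) -> MetricsReport:
    kc, kj, kd, st, sb = similarity_metrics(c)
    dn, df, ef = error_metrics(c)
    return MetricsReport(kc, kj, kd, st, sb, dn, df, ef)


def evaluate_masks(pred: np.ndarray, gold: np.ndarray) -> MetricsReport:
    """One-call evaluation of a predicted mask against a gold mask."""
    return report_from_counts(confusion_counts(pred, gold))


def aggregate_counts(counts: Iterable[ConfusionCounts]) -> ConfusionCounts:
    total = ConfusionCounts(0, 0, 0)
    for c in counts:
        total = total + c
    return total


def evaluate_stack(
    preds: Sequence[np.ndarray],
    golds: Sequence[np.ndarray],
    mode: str = "volumetric",
) -> MetricsReport:
    """Evaluate a stack (e.g. the eight slices of one subject).

    mode="volumetric" sums the confusion counts over the stack before
    computing metrics — the convention behind "volumetric Dice" reporting.
    mode="slicewise" averages the per-slice metric values instead.  The two
    differ whenever slice sizes are unbalanced.
    """
    if len(preds) != len(golds):
        raise ValueError("pred/gold stacks differ in length")
    if len(preds) == 0:
        raise ValueError("empty stack")
    counts = [confusion_counts(p, g) for p, g in zip(preds, golds)]
    if mode == "volumetric":
        return report_from_counts(aggregate_counts(counts))
    if mode == "slicewise":
        reports = [report_from_counts(c) for c in counts]
        mean = lambda xs: float(np.mean(xs))  # noqa: E731  (NaN propagates)
        return MetricsReport(
            mean([r.conformity for r in reports]),
            mean([r.jaccard for r in reports]),
            mean([r.dice for r in reports]),
            mean([r.sensitivity for r in reports]),
            mean([r.sensibility for r in reports]),
            mean([r.delta_n for r in reports]),
            mean([r.delta_f for r in reports]),
            mean([r.error_ratio for r in reports]),
        )
    raise ValueError(f"unknown mode {mode!r}")
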