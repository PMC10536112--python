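"""Segmentation agreement metrics.

White (1) pixels are the positive class (capillary).  The headline statistic
is the Jaccard index (intersection over union) between predicted and expert
masks; sensitivity, specificity and accuracy are reported alongside for
comparability with the capillaroscopy literature.

Conventions for degenerate masks: Jaccard is 1 when both masks are empty and
0 when exactly one is; sensitivity (resp. specificity) is 1 when the truth
contains no positives (resp. negatives) — nothing to miss.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "AggregateReport",
    "confusion",
    "report",
    "aggregate",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    jaccard: float
    sensitivity: float
    specificity: float
    accuracy: float
    counts: ConfusionCounts

    def as_dict(self) -> dict[str, float]:
        return {
            "jaccard": self.jaccard,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Per-pixel 2×2 tally of a predicted vs. a ground-truth binary mask."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    p = pred.astype(bool)
    t = truth.astype(bool)
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def report(counts: ConfusionCounts) -> MetricsReport:
    """Jaccard, sensitivity, specificity and accuracy from pixel counts."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    union = counts.tp + counts.fp + counts.fn
    jaccard = counts.tp / union if union > 0 else 1.0
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    sensitivity = counts.tp / pos if pos > 0 else 1.0
    specificity = counts.tn / neg if neg > 0 else 1.0
    accuracy = (counts.tp + counts.tn) / counts.total
    return MetricsReport(jaccard, sensitivity, specificity, accuracy, counts)


@dataclasses.dataclass(frozen=True)
class AggregateReport:
    """Cross-fold summary: unweighted mean of per-fold metrics (headline) and
    the pooled-counts variant (one confusion table over all pixels)."""

    fold_mean: MetricsReport
    pooled: MetricsReport
    n_folds: int

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            "fold_mean": self.fold_mean.as_dict(),
            "pooled": self.pooled.as_dict(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def aggregate(fold_reports: Sequence[MetricsReport]) -> AggregateReport:
    """Combine per-fold reports; the two variants differ when folds have
    unequal pixel counts."""
    if not fold_reports:
        raise ValueError("no folds to aggregate")
    pooled_counts = fold_reports[0].counts
    for r in fold_reports[1:]:
        pooled_counts = pooled_counts + r.counts
    pooled = report(pooled_counts)
    mean = MetricsReport(
        jaccard=float(np.mean([r.jaccard for r in fold_reports])),
        sensitivity=float(np.mean([r.sensitivity for r in fold_reports])),
        specificity=float(np.mean([r.specificity for r in fold_reports])),
        accuracy=float(np.mean([r.accuracy for r in fold_reports])),
        counts=pooled_counts,
    )
    return AggregateReport(fold_mean=mean, pooled=pooled, n_folds=len(fold_reports))
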