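"""Binary segmentation metrics for tissue-detection validation.

All metrics derive from the pixel confusion counts between a predicted and
a ground-truth binary mask (foreground = positive):

    Sensitivity = TP / (TP + FN)
    Precision   = TP / (TP + FP)
    F1          = 2 TP / (2 TP + FP + FN)
    IoU         = TP / (TP + FP + FN)

F1 is the harmonic mean of sensitivity and precision and relates to IoU by
F1 = 2 IoU / (1 + IoU).  When a denominator is zero the metric is 0 by
default (the worst-case reading); pass ``empty_value=1.0`` to score two
empty masks as a perfect match instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .image_io import binarize

logger = logging.getLogger(__name__)

METRIC_NAMES = ("sensitivity", "precision", "f1", "iou")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-level TP/FP/TN/FN counts between two binary masks."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally pixel confusion counts; masks must share dimensions."""
    p = binarize(np.asarray(pred)) > 0
    t = binarize(np.asarray(truth)) > 0
    if p.shape != t.shape:
        raise ValueError(f"mask shapes differ: pred {p.shape} vs truth {t.shape}")
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(p.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, empty_value: float) -> float:
    return num / den if den > 0 else empty_value


def sensitivity(c: ConfusionCounts, empty_value: float = 0.0) -> float:
    return _ratio(c.tp, c.tp + c.fn, empty_value)


def precision(c: ConfusionCounts, empty_value: float = 0.0) -> float:
    return _ratio(c.tp, c.tp + c.fp, empty_value)


def f1(c: ConfusionCounts, empty_value: float = 0.0) -> float:
    return _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, empty_value)


def iou(c: ConfusionCounts, empty_value: float = 0.0) -> float:
    return _ratio(c.tp, c.tp + c.fp + c.fn, empty_value)


def metrics_report(c: ConfusionCounts, empty_value: float = 0.0) -> dict[str, float]:
    """All four metrics for one confusion-count object."""
    return {
        "sensitivity": sensitivity(c, empty_value),
        "precision": precision(c, empty_value),
        "f1": f1(c, empty_value),
        "iou": iou(c, empty_value),
    }


def evaluate_by_category(
    pairs: Iterable[tuple[np.ndarray, np.ndarray, str]],
    *,
    sample_std: bool = False,
    empty_value: float = 0.0,
) -> dict[str, dict[str, dict[str, float]]]:
    """Per-category mean and standard deviation of each per-image metric.

    ``pairs`` yields (pred_mask, truth_mask, category).  Metrics are
    computed per image and aggregated per category; the standard deviation
    is the population one (divide by n) unless ``sample_std`` is set.
    Returns ``{category: {metric: {"mean": m, "std": s}, "n": count}}``.
    """
    per_cat: dict[str, list[dict[str, float]]] = {}
    for pred, truth, category in pairs:
        scores = metrics_report(confusion_counts(pred, truth), empty_value)
        per_cat.setdefault(category, []).append(scores)

    report: dict[str, dict] = {}
    for category, rows in per_cat.items():
        if not rows:
            logger.warning("category %r has no samples; omitted", category)
            continue
        entry: dict = {"n": len(rows)}
        ddof = 1 if sample_std else 0
        for name in METRIC_NAMES:
            values = np.array([row[name] for row in rows], dtype=float)
            std = float(values.std(ddof=ddof)) if len(values) > ddof else 0.0
            entry[name] = {"mean": float(values.mean()), "std": std}
        report[category] = entry
    return report


def pooled_metrics(
    pairs: Iterable[tuple[np.ndarray, np.ndarray, str]],
    empty_value: float = 0.0,
) -> dict[str, dict[str, float]]:
    """Per-category metrics over pooled pixel counts (alternative to the
    per-image averaging of :func:`evaluate_by_category`)."""
    sums: dict[str, list[int]] = {}
    for pred, truth, category in pairs:
        c = confusion_counts(pred, truth)
        acc = sums.setdefault(category, [0, 0, 0, 0])
        acc[0] += c.tp
        acc[1] += c.fp
        acc[2] += c.tn
        acc[3] += c.fn
    return {
        cat: metrics_report(ConfusionCounts(*acc), empty_value)
        for cat, acc in sums.items()
    }
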