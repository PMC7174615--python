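"""Pixel-level segmentation scores: accuracy, precision, recall, IoU and
F-measure from the confusion counts of a predicted vs ground-truth mask.

Dataset summaries average per image (matching how mean scores are usually
reported for test sets); a pixel-pooled mode is available as a flag.
Undefined ratios (zero denominators) are reported as NaN and excluded from
aggregation rather than coerced to 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts",
           "metrics_from_counts", "iou", "evaluate_masks", "aggregate_reports"]

METRIC_NAMES = ("accuracy", "precision", "recall", "iou", "f_measure")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    iou: float
    f_measure: float
    counts: ConfusionCounts

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _check_binary_pair(predicted, truth):
    p = np.asarray(predicted)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    p = p.astype(bool)
    t = t.astype(bool)
    return p, t


def confusion_counts(predicted, truth) -> ConfusionCounts:
    """Per-pixel TP/TN/FP/FN tally of two equal-shape binary masks."""
    p, t = _check_binary_pair(predicted, truth)
    tp = int(np.count_nonzero(p & t))
    tn = int(np.count_nonzero(~p & ~t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics_from_counts(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, precision, recall, IoU and F-measure from confusion counts."""
    if counts.total <= 0:
        raise ValueError("confusion counts are all zero")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f = math.nan if (math.isnan(precision) or math.isnan(recall)) else 0.0
    else:
        f = 2.0 * precision * recall / (precision + recall)
    return MetricReport(
        accuracy=(tp + tn) / counts.total,
        precision=precision,
        recall=recall,
        iou=_ratio(tp, tp + fp + fn),
        f_measure=f,
        counts=counts,
    )


def iou(predicted, truth) -> float:
    """Intersection over union of the positive pixel sets."""
    p, t = _check_binary_pair(predicted, truth)
    union = int(np.count_nonzero(p | t))
    if union == 0:
        raise ValueError("IoU undefined: both masks are empty")
    return int(np.count_nonzero(p & t)) / union


def evaluate_masks(predicted, truth) -> MetricReport:
    return metrics_from_counts(confusion_counts(predicted, truth))


def aggregate_reports(reports, pooled: bool = False) -> dict:
    """Summarize per-image reports.

    Default: per-metric mean and standard deviation over images, skipping
    NaN (undefined) entries and counting them.  ``pooled=True`` instead sums
    confusion counts over all images and evaluates once.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to aggregate")
    if pooled:
        tot = ConfusionCounts(
            sum(r.counts.tp for r in reports), sum(r.counts.tn for r in reports),
            sum(r.counts.fp for r in reports), sum(r.counts.fn for r in reports))
        rep = metrics_from_counts(tot)
        return {"mode": "pooled", "n_images": len(reports), **rep.as_dict()}
    out: dict = {"mode": "per_image", "n_images": len(reports)}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        ok = vals[~np.isnan(vals)]
        out[f"{name}_mean"] = float(ok.mean()) if ok.size else math.nan
        out[f"{name}_sd"] = float(ok.std(ddof=0)) if ok.size else math.nan
        out[f"{name}_undefined"] = int(np.isnan(vals).sum())
    return out
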