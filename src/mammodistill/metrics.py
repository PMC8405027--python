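"""Pixel-level segmentation metrics and TP/TN/FP/FN overlay rendering.

Predictions are binarized at 0.5 before tallying.  Five metrics are
reported: accuracy, recall, F1, specificity and IoU (Jaccard).  Any metric
whose denominator is zero is defined as 0 and flagged, so degenerate tiles
(e.g. an empty ground-truth mask) never divide by zero silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BINARIZE_THRESHOLD = 0.5

#: Fig-style overlay colors (RGB): TP blue, TN black, FP green, FN red.
OVERLAY_COLORS = {
    "tp": (0, 0, 255),
    "tn": (0, 0, 0),
    "fp": (0, 255, 0),
    "fn": (255, 0, 0),
}


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    """The five segmentation metrics, all in [0, 1].

    ``zero_denominator`` lists metrics that were forced to 0 because their
    defining ratio was 0/0 (e.g. recall on an empty ground-truth mask).
    """

    ac: float
    re: float
    f1: float
    sp: float
    iou: float
    n_images: int = 1
    aggregation: str = "single"
    zero_denominator: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"ac": self.ac, "re": self.re, "f1": self.f1,
                "sp": self.sp, "iou": self.iou,
                "n_images": self.n_images, "aggregation": self.aggregation}


def binarize(prob_map: np.ndarray, threshold: float = BINARIZE_THRESHOLD) -> np.ndarray:
    """Threshold a probability map to a {0,1} mask."""
    return (np.asarray(prob_map) > threshold).astype(np.uint8)


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if not np.all(np.isin(a, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1)")
    return a.astype(bool)


def confusion(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Exact TP/FP/TN/FN pixel tallies for a binary prediction vs ground truth."""
    p = _check_binary(pred_mask, "pred_mask")
    g = _check_binary(gt_mask, "gt_mask")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    fn = int(np.sum(~p & g))
    tn = int(np.sum(~p & ~g))
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Accuracy, recall, F1, specificity and IoU from one confusion table."""
    flags: list[str] = []
    ac = _ratio(c.tp + c.tn, c.total, "ac", flags)
    re = _ratio(c.tp, c.tp + c.fn, "re", flags)
    sp = _ratio(c.tn, c.fp + c.tn, "sp", flags)
    precision = _ratio(c.tp, c.tp + c.fp, "precision", flags)
    f1 = _ratio(2.0 * re * precision, re + precision, "f1", flags)
    iou = _ratio(c.tp, c.tp + c.fp + c.fn, "iou", flags)
    return MetricsReport(ac=ac, re=re, f1=f1, sp=sp, iou=iou,
                         zero_denominator=flags)


def evaluate_masks(pred_masks, gt_masks, aggregation: str = "per_image_mean") -> MetricsReport:
    """Dataset-level metrics over paired mask lists.

    ``per_image_mean`` averages each metric over images (the default
    report); ``pooled`` sums the confusion tables first and computes the
    metrics once on the pooled counts.
    """
    if aggregation not in ("per_image_mean", "pooled"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    counts = [confusion(p, g) for p, g in zip(pred_masks, gt_masks)]
    if not counts:
        raise ValueError("no mask pairs to evaluate")
    if aggregation == "pooled":
        pooled = counts[0]
        for c in counts[1:]:
            pooled = pooled + c
        rep = compute_metrics(pooled)
        rep.n_images = len(counts)
        rep.aggregation = "pooled"
        return rep
    reports = [compute_metrics(c) for c in counts]
    flags = sorted({f for r in reports for f in r.zero_denominator})
    return MetricsReport(
        ac=float(np.mean([r.ac for r in reports])),
        re=float(np.mean([r.re for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        sp=float(np.mean([r.sp for r in reports])),
        iou=float(np.mean([r.iou for r in reports])),
        n_images=len(reports),
        aggregation="per_image_mean",
        zero_denominator=flags,
    )


def overlay(pred_mask: np.ndarray, gt_mask: np.ndarray) -> np.ndarray:
    """Render the pixelwise agreement image: TP blue, TN black, FP green, FN red."""
    p = _check_binary(pred_mask, "pred_mask")
    g = _check_binary(gt_mask, "gt_mask")
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    img = np.zeros(p.shape + (3,), dtype=np.uint8)
    img[p & g] = OVERLAY_COLORS["tp"]
    img[p & ~g] = OVERLAY_COLORS["fp"]
    img[~p & g] = OVERLAY_COLORS["fn"]
    img[~p & ~g] = OVERLAY_COLORS["tn"]
    return img
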