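"""Segmentation evaluation: per-class IoU and Dice from pixel confusion.

For one class on one (prediction, reference) mask pair the pixel counts are

    TP = |pred ∩ ref|,  FP = |pred \\ ref|,  FN = |ref \\ pred|,

and the overlap scores are IoU = TP/(TP+FP+FN), Dice = 2TP/(2TP+FP+FN).
A class absent from both masks scores 1 by convention (configurable).
mIoU/mDice are arithmetic means over an explicit class set; the default
averages the three foreground anatomy classes and excludes background.

Two aggregation modes exist for a test set: ``macro`` (score each image,
average the scores — the default) and ``global`` (pool the pixel counts over
all images, score once).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PixelConfusion", "SegReport", "pixel_confusion", "iou", "dice",
           "mean_metrics", "evaluate_pair", "evaluate_dataset",
           "confusion_matrix_pixels"]


@dataclass(frozen=True)
class PixelConfusion:
    """Pixel counts for one class on one mask pair."""
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class SegReport:
    """Per-class and mean overlap scores for one evaluation."""
    per_class: dict          # class id -> (iou, dice)
    miou: float
    mdice: float
    include_background: bool
    k: int                   # number of classes averaged


def pixel_confusion(pred: np.ndarray, truth: np.ndarray,
                    class_id: int) -> PixelConfusion:
    """Exact pixel-set arithmetic for one class."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    p = pred == class_id
    t = truth == class_id
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = pred.size - tp - fp - fn
    return PixelConfusion(tp, fp, fn, tn)


def confusion_matrix_pixels(pred: np.ndarray, truth: np.ndarray,
                            num_classes: int) -> np.ndarray:
    """Dense (truth, pred) pixel count matrix for multi-class masks."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    idx = truth.astype(np.int64) * num_classes + pred.astype(np.int64)
    return np.bincount(idx, minlength=num_classes ** 2).reshape(
        num_classes, num_classes)


def iou(c: PixelConfusion, empty_value: float = 1.0) -> float:
    denom = c.tp + c.fp + c.fn
    return c.tp / denom if denom else empty_value


def dice(c: PixelConfusion, empty_value: float = 1.0) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else empty_value


def evaluate_pair(pred: np.ndarray, truth: np.ndarray, classes,
                  empty_value: float = 1.0) -> dict:
    """class id -> (iou, dice) on one mask pair."""
    out = {}
    for cls in classes:
        c = pixel_confusion(pred, truth, cls)
        out[cls] = (iou(c, empty_value), dice(c, empty_value))
    return out


def mean_metrics(per_class: dict, include_background: bool = False,
                 background_class: int = 0) -> SegReport:
    """Arithmetic means over the chosen class set (Eq.-style k-average)."""
    keys = sorted(per_class)
    if not include_background:
        keys = [c for c in keys if c != background_class]
    if not keys:
        raise ValueError("empty class set")
    miou = float(np.mean([per_class[c][0] for c in keys]))
    mdice = float(np.mean([per_class[c][1] for c in keys]))
    return SegReport(per_class={c: per_class[c] for c in keys},
                     miou=miou, mdice=mdice,
                     include_background=include_background, k=len(keys))


def evaluate_dataset(preds, truths, classes=(1, 2, 3),
                     include_background: bool = False,
                     aggregation: str = "macro",
                     empty_value: float = 1.0) -> SegReport:
    """Score a whole test set.

    ``macro``: compute IoU/Dice per image, then average over images.
    ``global``: pool pixel counts over all images first.
    """
    preds = list(preds)
    truths = list(truths)
    if len(preds) != len(truths) or not preds:
        raise ValueError("need equal, nonzero numbers of masks")
    all_classes = sorted(set(classes) | ({0} if include_background else set()))
    if aggregation == "global":
        agg = {}
        for cls in all_classes:
            tp = fp = fn = tn = 0
            for p, t in zip(preds, truths):
                c = pixel_confusion(p, t, cls)
                tp, fp, fn, tn = tp + c.tp, fp + c.fp, fn + c.fn, tn + c.tn
            c = PixelConfusion(tp, fp, fn, tn)
            agg[cls] = (iou(c, empty_value), dice(c, empty_value))
    elif aggregation == "macro":
        per_image = [evaluate_pair(p, t, all_classes, empty_value)
                     for p, t in zip(preds, truths)]
        agg = {cls: (float(np.mean([pi[cls][0] for pi in per_image])),
                     float(np.mean([pi[cls][1] for pi in per_image])))
               for cls in all_classes}
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return mean_metrics(agg, include_background=include_background)
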