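"""Detection evaluation: precision/recall/F1, PR curves, AP/mAP@0.5,
ROC/AUC, paired comparison, and per-side diagnosis rules.

Boxes are normalised centre-form (cx, cy, w, h) in [0,1].  Matching follows
the standard detection-evaluation convention: within each category,
detections are taken in order of descending confidence and each greedily
claims the unmatched ground-truth box of highest IoU at or above the
threshold (one-to-one).  Claimed detections are TP, unclaimed detections FP,
unclaimed truths FN.  TN is undefined for open-set detection and only enters
through the per-side binary diagnosis task, where each image side is one
trial.

AP is the area under the precision envelope of the PR curve (all-point
interpolation); an 11-point mode is exposed.  AUC is the normalised
Mann–Whitney U with ties counted half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .phantom import (CATEGORY_NAMES, CAT_FRACTURE_L, CAT_FRACTURE_R,
                      CAT_NONFRACTURE_L, CAT_NONFRACTURE_R)

__all__ = ["BoxAnnotation", "Detection", "DetectionConfusion", "MatchResult",
           "box_iou", "match_detections", "precision", "recall", "f1",
           "pr_curve", "average_precision", "mean_ap", "roc_auc",
           "paired_t_test", "diagnosis_from_detections", "CATEGORY_NAMES"]


@dataclass(frozen=True)
class BoxAnnotation:
    """Ground-truth box: category id (0..3) + normalised centre form."""
    category: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError("box width and height must be positive")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        return (self.cx - self.w / 2, self.cy - self.h / 2,
                self.cx + self.w / 2, self.cy + self.h / 2)


@dataclass(frozen=True)
class Detection(BoxAnnotation):
    """A detector output: box + confidence score."""
    confidence: float = 1.0

    def __post_init__(self):
        super().__post_init__()
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0,1]")


@dataclass(frozen=True)
class DetectionConfusion:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    def __add__(self, other: "DetectionConfusion") -> "DetectionConfusion":
        return DetectionConfusion(self.tp + other.tp, self.fp + other.fp,
                                  self.fn + other.fn)


@dataclass(frozen=True)
class MatchResult:
    per_category: dict       # category -> DetectionConfusion
    matches: list            # (det index, truth index) pairs
    det_is_tp: list          # bool per detection (original order)

    @property
    def pooled(self) -> DetectionConfusion:
        total = DetectionConfusion(0, 0, 0)
        for c in self.per_category.values():
            total = total + c
        return total


def box_iou(a, b) -> float:
    """Continuous-coordinate intersection-over-union of two boxes."""
    ax0, ay0, ax1, ay1 = a.corners if hasattr(a, "corners") else a
    bx0, by0, bx1, by1 = b.corners if hasattr(b, "corners") else b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union


def match_detections(dets, truths, iou_threshold: float = 0.5) -> MatchResult:
    """Greedy confidence-descending one-to-one matching per category."""
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in (0,1]")
    dets = list(dets)
    truths = list(truths)
    categories = sorted({d.category for d in dets} |
                        {t.category for t in truths})
    per_cat: dict = {}
    matches: list = []
    det_is_tp = [False] * len(dets)
    for cat in categories:
        d_idx = [i for i, d in enumerate(dets) if d.category == cat]
        t_idx = [j for j, t in enumerate(truths) if t.category == cat]
        d_idx.sort(key=lambda i: -dets[i].confidence)  # stable: index breaks ties
        claimed: set = set()
        tp = 0
        for i in d_idx:
            best_j, best_iou = None, 0.0
            for j in t_idx:
                if j in claimed:
                    continue
                v = box_iou(dets[i], truths[j])
                if v >= iou_threshold and v > best_iou:
                    best_j, best_iou = j, v
            if best_j is not None:
                claimed.add(best_j)
                matches.append((i, best_j))
                det_is_tp[i] = True
                tp += 1
        per_cat[cat] = DetectionConfusion(
            tp=tp, fp=len(d_idx) - tp, fn=len(t_idx) - tp)
    return MatchResult(per_category=per_cat, matches=matches,
                       det_is_tp=det_is_tp)


def precision(c: DetectionConfusion) -> float:
    return c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0


def recall(c: DetectionConfusion) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0


def f1(c: DetectionConfusion) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    return 2 * c.tp / denom if denom else 0.0


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of precision and recall."""
    return 2 * p * r / (p + r) if p + r else 0.0


def pr_curve(dets, truths, iou_threshold: float = 0.5,
             category: int | None = None) -> list[tuple[float, float]]:
    """(recall, precision) after each detection of the confidence sweep."""
    dets = [d for d in dets if category is None or d.category == category]
    truths = [t for t in truths if category is None or t.category == category]
    if not truths:
        raise ValueError("PR curve needs at least one ground-truth box")
    flags = match_detections(dets, truths, iou_threshold).det_is_tp
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    curve = []
    tp = fp = 0
    for i in order:
        if flags[i]:
            tp += 1
        else:
            fp += 1
        curve.append((tp / len(truths), tp / (tp + fp)))
    return curve


def average_precision(curve, interpolation: str = "all_point") -> float:
    """Area under the precision envelope of a PR curve.

    ``all_point``: precision at recall r is the maximum precision at any
    recall >= r, integrated exactly over recall.  ``11_point``: the same
    envelope sampled at recalls 0, 0.1, ..., 1 and averaged.
    """
    if not curve:
        return 0.0
    rs = np.array([r for r, _ in curve])
    ps = np.array([p for _, p in curve])
    order = np.argsort(rs, kind="stable")
    rs, ps = rs[order], ps[order]
    env = np.maximum.accumulate(ps[::-1])[::-1]   # max precision at >= recall
    if interpolation == "11_point":
        samples = []
        for r in np.linspace(0.0, 1.0, 11):
            mask = rs >= r - 1e-12
            samples.append(env[mask][0] if mask.any() else 0.0)
        return float(np.mean(samples))
    if interpolation != "all_point":
        raise ValueError(f"unknown interpolation {interpolation!r}")
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(rs, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_ap(per_category_ap: dict) -> float:
    if not per_category_ap:
        raise ValueError("empty AP map")
    return float(np.mean(list(per_category_ap.values())))


def roc_auc(scores, labels) -> float:
    """AUC as the normalised Mann–Whitney U statistic (midranks for ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc needs both label values present")
    ranks = stats.rankdata(scores)       # midranks
    u = ranks[pos].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n0 * n1))


def paired_t_test(before, after) -> tuple[float, float]:
    """Two-sided paired t-test on (before - after) differences.

    The t statistic is positive when ``before`` exceeds ``after`` on
    average, i.e. negative for an improvement.  Zero-variance differences
    are degenerate and raise.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape:
        raise ValueError("length mismatch")
    if len(before) < 2:
        raise ValueError("need at least two pairs")
    if np.ptp(before - after) == 0.0:
        raise ValueError("zero-variance differences: t-test degenerate")
    res = stats.ttest_rel(before, after)
    return float(res.statistic), float(res.pvalue)


_SIDE_OF_CATEGORY = {CAT_FRACTURE_R: "R", CAT_NONFRACTURE_R: "R",
                     CAT_FRACTURE_L: "L", CAT_NONFRACTURE_L: "L"}
_FRACTURE_CATEGORIES = {CAT_FRACTURE_R, CAT_FRACTURE_L}


def diagnosis_from_detections(dets, rule: str = "highest_confidence") -> dict:
    """Turn an image's detections into one binary fracture call per side.

    For each side, the highest-confidence detection on that side decides;
    a side with no detections is called non-fracture.
    """
    if rule != "highest_confidence":
        raise ValueError(f"unknown rule {rule!r}")
    calls = {"R": False, "L": False}
    best = {"R": -1.0, "L": -1.0}
    for d in dets:
        side = _SIDE_OF_CATEGORY[d.category]
        if d.confidence > best[side]:
            best[side] = d.confidence
            calls[side] = d.category in _FRACTURE_CATEGORIES
    return calls
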