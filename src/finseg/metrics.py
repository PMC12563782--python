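"""Evaluation kernels: recall/precision, AP/mAP, mIoU, PA, fps, paired t.

Detection matching follows the standard convention: predictions are
ranked by confidence and greedily matched to the unmatched ground truth
of the same class with the highest IoU above threshold; FP is a
predicted positive with no matching truth and FN a truth with no
matching prediction (the only reading under which precision is
``TP / (TP + FP)``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .annotations import BoundingBox

__all__ = [
    "MatchCounts",
    "MetricReport",
    "box_iou",
    "match_detections",
    "average_precision",
    "mean_average_precision",
    "detection_map",
    "confusion_matrix",
    "mean_iou",
    "pixel_accuracy",
    "segmentation_class_precision",
    "throughput",
    "paired_t_test",
]


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0


@dataclass
class PairedTResult:
    statistic: float
    df: int
    p_value: float
    degenerate: bool = False


@dataclass
class MetricReport:
    per_class_ap: dict = field(default_factory=dict)
    map50: float = float("nan")
    per_class_iou: dict = field(default_factory=dict)
    miou: float = float("nan")
    pixel_accuracy: float = float("nan")
    fps: float = float("nan")
    paired_t: PairedTResult | None = None


def box_iou(a: BoundingBox | np.ndarray, b: BoundingBox | np.ndarray) -> float:
    ax = a.as_array() if isinstance(a, BoundingBox) else np.asarray(a, float)
    bx = b.as_array() if isinstance(b, BoundingBox) else np.asarray(b, float)
    ix = max(0.0, min(ax[2], bx[2]) - max(ax[0], bx[0]))
    iy = max(0.0, min(ax[3], bx[3]) - max(ax[1], bx[1]))
    inter = ix * iy
    union = ((ax[2] - ax[0]) * (ax[3] - ax[1])
             + (bx[2] - bx[0]) * (bx[3] - bx[1]) - inter)
    return inter / union if union > 0 else 0.0


def match_detections(
    preds: Sequence[Sequence[BoundingBox]],
    gts: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
):
    """Greedy confidence-ranked matching over a set of images.

    ``preds[i]`` and ``gts[i]`` hold the boxes of image ``i``.  Returns
    ``(MatchCounts, flags)`` where ``flags`` is the ranked list of
    ``(confidence, is_tp, class_id)`` needed for AP computation.
    """
    if len(preds) != len(gts):
        raise ValueError("pred and gt image counts differ")
    ranked = sorted(
        ((img, j, b) for img, boxes in enumerate(preds) for j, b in enumerate(boxes)),
        key=lambda t: (-t[2].confidence, t[0], t[1]),
    )
    matched: set[tuple[int, int]] = set()
    flags = []
    for img, _, pb in ranked:
        best, best_iou = None, iou_threshold
        for gj, gb in enumerate(gts[img]):
            if gb.class_id != pb.class_id or (img, gj) in matched:
                continue
            i = box_iou(pb, gb)
            if i >= best_iou:
                best, best_iou = gj, i
        if best is not None:
            matched.add((img, best))
            flags.append((pb.confidence, True, pb.class_id))
        else:
            flags.append((pb.confidence, False, pb.class_id))
    n_gt = sum(len(g) for g in gts)
    tp = sum(1 for _, ok, _ in flags if ok)
    return MatchCounts(tp=tp, fp=len(flags) - tp, fn=n_gt - tp), flags


def average_precision(tp_flags: Sequence[bool], n_gt: int,
                      method: str = "all_point") -> float:
    """Area under the precision–recall curve of a ranked detection list.

    ``all_point`` integrates the monotone precision envelope over every
    recall step; ``11point`` averages the envelope at recalls
    0, 0.1, ..., 1.0.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    flags = np.asarray(tp_flags, dtype=bool)
    if n_gt == 0:
        return 0.0 if flags.size else float("nan")
    if flags.size == 0:
        return 0.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # monotone non-increasing envelope
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if method == "11point":
        pts = [env[recall >= r].max(initial=0.0) for r in np.linspace(0, 1, 11)]
        return float(np.mean(pts))
    if method != "all_point":
        raise ValueError(f"unknown AP method {method!r}")
    r_prev = 0.0
    area = 0.0
    for i in range(len(recall)):
        if recall[i] > r_prev:
            area += (recall[i] - r_prev) * env[i]
            r_prev = recall[i]
    return float(area)


def mean_average_precision(per_class_ap: dict[int, float]) -> float:
    """Unweighted mean over classes present in the ground truth (non-NaN)."""
    if not per_class_ap:
        raise ValueError("no classes")
    vals = [v for v in per_class_ap.values() if not math.isnan(v)]
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def detection_map(
    preds: Sequence[Sequence[BoundingBox]],
    gts: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
    method: str = "all_point",
) -> tuple[float, dict[int, float]]:
    """mAP at one IoU threshold plus the per-class AP breakdown."""
    classes = sorted({b.class_id for g in gts for b in g}
                     | {b.class_id for p in preds for b in p})
    per_class: dict[int, float] = {}
    for c in classes:
        pc = [[b for b in boxes if b.class_id == c] for boxes in preds]
        gc = [[b for b in boxes if b.class_id == c] for boxes in gts]
        n_gt = sum(len(g) for g in gc)
        _, flags = match_detections(pc, gc, iou_threshold)
        per_class[c] = average_precision([ok for _, ok, _ in flags], n_gt, method)
    return mean_average_precision(per_class), per_class


def confusion_matrix(pred_mask: np.ndarray, gt_mask: np.ndarray, k: int) -> np.ndarray:
    """(k+1) x (k+1) pixel confusion matrix, rows = truth, cols = prediction."""
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch {pred_mask.shape} vs {gt_mask.shape}")
    n = k + 1
    idx = gt_mask.astype(np.int64).ravel() * n + pred_mask.astype(np.int64).ravel()
    return np.bincount(idx, minlength=n * n).reshape(n, n)


def mean_iou(pred_mask: np.ndarray, gt_mask: np.ndarray, k: int):
    """Per-class IoU and their mean over the k+1 classes incl. background.

    Classes absent from both masks contribute NaN and are excluded from
    the mean.
    """
    cm = confusion_matrix(pred_mask, gt_mask, k)
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    denom = tp + fp + fn
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(denom > 0, tp / denom, np.nan)
    per_class = {c: float(iou[c]) for c in range(k + 1)}
    present = iou[~np.isnan(iou)]
    return per_class, (float(np.mean(present)) if present.size else float("nan"))


def pixel_accuracy(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Fraction of pixels whose predicted label matches the truth."""
    if pred_mask.shape != gt_mask.shape:
        raise ValueError(f"shape mismatch {pred_mask.shape} vs {gt_mask.shape}")
    return float(np.mean(pred_mask == gt_mask))


def segmentation_class_precision(pred_mask: np.ndarray, gt_mask: np.ndarray,
                                 k: int) -> tuple[float, dict[int, float]]:
    """Per-class pixel precision averaged over foreground classes.

    A dense-prediction analogue of detection mAP for reporting purposes:
    with argmax decisions there is no confidence ranking, so the
    precision of each class's predicted pixel set stands in for its AP.
    """
    cm = confusion_matrix(pred_mask, gt_mask, k)
    tp = np.diag(cm).astype(float)
    pred_pos = cm.sum(axis=0)
    per = {}
    for c in range(1, k + 1):
        per[c] = float(tp[c] / pred_pos[c]) if pred_pos[c] else float("nan")
    vals = [v for v in per.values() if not math.isnan(v)]
    return (float(np.mean(vals)) if vals else float("nan")), per


def throughput(n_images: int, seconds: float) -> float:
    """Frames per second: N / T."""
    if seconds <= 0:
        raise ValueError("elapsed time must be positive")
    return n_images / seconds


def paired_t_test(scores_a: Sequence[float], scores_b: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test on per-sample metric differences."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length 1-d score lists with n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0:
        return PairedTResult(0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean()),
                             n - 1, float("nan"), degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(float(t), n - 1, float(p))
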