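"""COCO-convention precision/recall and average-precision metrics.

AP is the area under the precision-recall curve realized by the COCO
convention: the precision envelope sampled at 101 recall thresholds
[0, 0.01, ..., 1].  mAP averages AP over the IoU thresholds 0.5:0.05:0.95;
AP50/AP75 fix the threshold; APm/APl restrict to the COCO medium
([32^2, 96^2]) and large (> 96^2) area ranges with proper ignore semantics
(out-of-range ground truth is ignored rather than counted, and unmatched
detections outside the range do not count as false positives).

Undefined metrics (no ground truth in range) are reported as -1.0, matching
the reference COCO tooling's sentinel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxes import iou_matrix

__all__ = [
    "IOU_THRESHOLDS",
    "RECALL_THRESHOLDS",
    "AREA_RANGES",
    "MatchCounts",
    "PRCurve",
    "MetricsReport",
    "match_at_threshold",
    "precision_recall_curve",
    "average_precision",
    "ap_at_threshold",
    "coco_summary",
]

IOU_THRESHOLDS = np.round(np.arange(0.5, 0.96, 0.05), 2)
RECALL_THRESHOLDS = np.linspace(0.0, 1.0, 101)
AREA_RANGES = {
    "all": (0.0, 1e10),
    "small": (0.0, 32.0**2),
    "medium": (32.0**2, 96.0**2),
    "large": (96.0**2, 1e10),
}
MAX_DETECTIONS_PER_IMAGE = 100


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int


@dataclass(frozen=True)
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray


@dataclass(frozen=True)
class MetricsReport:
    mAP: float
    ap50: float
    ap75: float
    ap_m: float
    ap_l: float
    ap_s: float | None = None

    def to_dict(self) -> dict:
        d = {"mAP": self.mAP, "AP50": self.ap50, "AP75": self.ap75,
             "APm": self.ap_m, "APl": self.ap_l}
        if self.ap_s is not None:
            d["APs"] = self.ap_s
        return d


def _as_box_score_arrays(dets):
    """Accept a list of Detection-likes or an (N, 5) array [x0,y0,x1,y1,score]."""
    if isinstance(dets, np.ndarray):
        dets = np.asarray(dets, dtype=np.float64).reshape(-1, 5)
        return dets[:, :4], dets[:, 4]
    boxes = np.asarray([list(d.box) for d in dets], dtype=np.float64).reshape(-1, 4)
    scores = np.asarray([d.score for d in dets], dtype=np.float64)
    return boxes, scores


def match_at_threshold(det_boxes: np.ndarray, gt_boxes: np.ndarray, iou_thr: float,
                       gt_ignore: np.ndarray | None = None,
                       det_area_range: tuple | None = None):
    """Greedy matching of score-ordered detections to ground truth.

    Each detection takes the highest-IoU still-unmatched ground truth with
    IoU >= threshold (preferring non-ignored ground truth); each ground truth
    is used at most once.  Returns ``(MatchCounts, tp_flags, ignore_flags)``
    where flags follow the detection order.  Detections must already be
    sorted by descending score.
    """
    det_boxes = np.asarray(det_boxes, dtype=np.float64).reshape(-1, 4)
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    nd, ng = len(det_boxes), len(gt_boxes)
    if gt_ignore is None:
        gt_ignore = np.zeros(ng, dtype=bool)
    # evaluate non-ignored ground truth first
    gt_order = np.argsort(gt_ignore, kind="stable")
    ious = iou_matrix(det_boxes, gt_boxes) if nd and ng else np.zeros((nd, ng))

    gt_matched = np.full(ng, -1, dtype=np.int64)
    det_matched = np.full(nd, -1, dtype=np.int64)
    det_ignore = np.zeros(nd, dtype=bool)
    for d in range(nd):
        best_iou = min(iou_thr, 1.0 - 1e-10)
        best_g = -1
        for g in gt_order:
            if gt_matched[g] >= 0:
                continue
            if best_g > -1 and not gt_ignore[best_g] and gt_ignore[g]:
                break
            if ious[d, g] < best_iou:
                continue
            best_iou = ious[d, g]
            best_g = g
        if best_g == -1:
            continue
        det_matched[d] = best_g
        det_ignore[d] = gt_ignore[best_g]
        gt_matched[best_g] = d
    if det_area_range is not None and nd:
        areas = (det_boxes[:, 2] - det_boxes[:, 0]) * (det_boxes[:, 3] - det_boxes[:, 1])
        out = (areas < det_area_range[0]) | (areas > det_area_range[1])
        det_ignore |= out & (det_matched == -1)
    tp_flags = (det_matched >= 0) & ~det_ignore
    n_gt_considered = int((~gt_ignore).sum())
    tp = int(tp_flags.sum())
    fp = int((~tp_flags & ~det_ignore).sum())
    counts = MatchCounts(tp=tp, fp=fp, fn=n_gt_considered - tp)
    return counts, tp_flags, det_ignore


def precision_recall_curve(tp_flags: np.ndarray, n_gt: int) -> PRCurve:
    """Cumulative precision/recall at every detection rank (score order)."""
    tp_flags = np.asarray(tp_flags, dtype=bool)
    if n_gt == 0:
        return PRCurve(recall=np.zeros(0), precision=np.zeros(0))
    tp_cum = np.cumsum(tp_flags)
    ranks = np.arange(1, len(tp_flags) + 1)
    return PRCurve(recall=tp_cum / n_gt, precision=tp_cum / ranks)


def average_precision(curve: PRCurve) -> float:
    """101-point interpolated AP of a cumulative PR curve."""
    if len(curve.recall) == 0:
        return 0.0
    precision = curve.precision.copy()
    # precision envelope: running maximum from the right
    precision = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(curve.recall, RECALL_THRESHOLDS, side="left")
    sampled = np.where(idx < len(precision), precision[np.minimum(idx, len(precision) - 1)], 0.0)
    return float(sampled.mean())


def ap_at_threshold(detections: dict, gts: dict, iou_thr: float,
                    area_range: tuple | None = None,
                    max_dets: int = MAX_DETECTIONS_PER_IMAGE) -> tuple[float, PRCurve]:
    """AP (and the underlying PR curve) over a whole dataset at one threshold.

    ``detections`` maps image id to a detection list; ``gts`` maps image id to
    an (N, 4) box array.  Detection lists are truncated to ``max_dets`` per
    image by score.  Returns ``(-1.0, empty curve)`` if no ground truth falls
    in the area range.
    """
    lo, hi = area_range if area_range is not None else AREA_RANGES["all"]
    all_scores, all_flags, all_ignore = [], [], []
    n_gt = 0
    for image_id in sorted(gts):
        gt_boxes = np.asarray(gts[image_id], dtype=np.float64).reshape(-1, 4)
        areas = (gt_boxes[:, 2] - gt_boxes[:, 0]) * (gt_boxes[:, 3] - gt_boxes[:, 1])
        gt_ignore = (areas < lo) | (areas > hi)
        n_gt += int((~gt_ignore).sum())
        boxes, scores = _as_box_score_arrays(detections.get(image_id, []))
        order = np.argsort(-scores, kind="stable")[:max_dets]
        boxes, scores = boxes[order], scores[order]
        _, tp_flags, det_ignore = match_at_threshold(
            boxes, gt_boxes, iou_thr, gt_ignore=gt_ignore, det_area_range=(lo, hi)
        )
        all_scores.append(scores)
        all_flags.append(tp_flags)
        all_ignore.append(det_ignore)
    if n_gt == 0:
        return -1.0, PRCurve(recall=np.zeros(0), precision=np.zeros(0))
    scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
    flags = np.concatenate(all_flags) if all_flags else np.zeros(0, dtype=bool)
    ignore = np.concatenate(all_ignore) if all_ignore else np.zeros(0, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    flags, ignore = flags[order], ignore[order]
    flags = flags[~ignore]
    curve = precision_recall_curve(flags, n_gt)
    return average_precision(curve), curve


def coco_summary(detections: dict, gts: dict, include_small: bool = False,
                 max_dets: int = MAX_DETECTIONS_PER_IMAGE) -> MetricsReport:
    """Full metrics report: mAP@[0.5:0.05:0.95], AP50, AP75, APm, APl."""
    total_gt = sum(len(np.asarray(g).reshape(-1, 4)) for g in gts.values())
    if total_gt == 0:
        warnings.warn("no ground-truth boxes; metrics are undefined", stacklevel=2)
        return MetricsReport(0.0, 0.0, 0.0, -1.0, -1.0,
                             ap_s=-1.0 if include_small else None)
    aps = [
        ap_at_threshold(detections, gts, thr, max_dets=max_dets)[0]
        for thr in IOU_THRESHOLDS
    ]
    m_aps = [
        np.mean([
            ap_at_threshold(detections, gts, thr, AREA_RANGES[rng_name],
                            max_dets=max_dets)[0]
            for thr in IOU_THRESHOLDS
        ]) if _any_gt_in_range(gts, AREA_RANGES[rng_name]) else -1.0
        for rng_name in ("medium", "large", "small")
    ]
    return MetricsReport(
        mAP=float(np.mean(aps)),
        ap50=aps[0],
        ap75=aps[5],
        ap_m=float(m_aps[0]),
        ap_l=float(m_aps[1]),
        ap_s=float(m_aps[2]) if include_small else None,
    )


def _any_gt_in_range(gts: dict, area_range: tuple) -> bool:
    lo, hi = area_range
    for g in gts.values():
        g = np.asarray(g, dtype=np.float64).reshape(-1, 4)
        if len(g) == 0:
            continue
        areas = (g[:, 2] - g[:, 0]) * (g[:, 3] - g[:, 1])
        if ((areas >= lo) & (areas <= hi)).any():
            return True
    return False
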