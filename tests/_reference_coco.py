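"""Reference COCO-style evaluator, transcribed independently from the
published COCO evaluation algorithm (per-image greedy matching, per-detection
ignore flags, 101-point interpolated precision envelope).

This module deliberately mirrors the reference tooling's control flow
(nested loops, per-image eval then accumulate) rather than the vectorized
implementation under test.
"""

from __future__ import annotations

import numpy as np

IOU_THRS = [round(0.5 + 0.05 * i, 2) for i in range(10)]
REC_THRS = list(np.linspace(0.0, 1.0, 101))  # matches the COCO tooling exactly


def _iou(a, b):
    ix0 = max(a[0], b[0])
    iy0 = max(a[1], b[1])
    ix1 = min(a[2], b[2])
    iy1 = min(a[3], b[3])
    iw = max(ix1 - ix0, 0.0)
    ih = max(iy1 - iy0, 0.0)
    inter = iw * ih
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def _evaluate_image(dets, gts, thr, area_range, max_dets):
    """dets: list of (box, score) already in input order; gts: list of boxes.

    Returns (det_scores, det_matched, det_ignored, n_gt_not_ignored).
    """
    lo, hi = area_range
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])[:max_dets]
    dets = [dets[i] for i in order]
    gt_ig = []
    for g in gts:
        area = (g[2] - g[0]) * (g[3] - g[1])
        gt_ig.append(area < lo or area > hi)
    gt_order = sorted(range(len(gts)), key=lambda i: gt_ig[i])

    gtm = [False] * len(gts)
    dtm = [-1] * len(dets)
    dt_ig = [False] * len(dets)
    for d, (dbox, _score) in enumerate(dets):
        best = min(thr, 1.0 - 1e-10)
        match = -1
        for g in gt_order:
            if gtm[g]:
                continue
            if match > -1 and not gt_ig[match] and gt_ig[g]:
                break
            iou = _iou(dbox, gts[g])
            if iou < best:
                continue
            best = iou
            match = g
        if match > -1:
            dtm[d] = match
            dt_ig[d] = gt_ig[match]
            gtm[match] = True
    for d, (dbox, _score) in enumerate(dets):
        area = (dbox[2] - dbox[0]) * (dbox[3] - dbox[1])
        if dtm[d] == -1 and (area < lo or area > hi):
            dt_ig[d] = True
    scores = [s for _, s in dets]
    matched = [m >= 0 for m in dtm]
    n_gt = sum(1 for ig in gt_ig if not ig)
    return scores, matched, dt_ig, n_gt


def reference_ap(detections, gts, thr, area_range=(0.0, 1e10), max_dets=100):
    """AP at one IoU threshold over a dataset (dicts keyed by image id)."""
    scores, matched, ignored = [], [], []
    npig = 0
    for image_id in sorted(gts):
        dets = detections.get(image_id, [])
        dets = [(list(d.box), float(d.score)) for d in dets] \
            if dets and hasattr(dets[0], "box") else list(dets)
        s, m, ig, n = _evaluate_image(dets, [list(g) for g in np.asarray(gts[image_id]).reshape(-1, 4)],
                                      thr, area_range, max_dets)
        scores += s
        matched += m
        ignored += ig
        npig += n
    if npig == 0:
        return -1.0
    order = np.argsort(-np.asarray(scores), kind="mergesort")
    tps = np.array([matched[i] and not ignored[i] for i in order])
    fps = np.array([(not matched[i]) and not ignored[i] for i in order])
    tp_sum = np.cumsum(tps)
    fp_sum = np.cumsum(fps)
    rc = tp_sum / npig
    pr = tp_sum / np.maximum(tp_sum + fp_sum, 1e-300)
    # precision envelope
    pr = list(pr)
    for i in range(len(pr) - 1, 0, -1):
        if pr[i] > pr[i - 1]:
            pr[i - 1] = pr[i]
    inds = np.searchsorted(rc, REC_THRS, side="left")
    q = [0.0] * len(REC_THRS)
    for ri, pi in enumerate(inds):
        if pi < len(pr):
            q[ri] = pr[pi]
    return float(np.mean(q))


def reference_summary(detections, gts, max_dets=100):
    """mAP / AP50 / AP75 / APm / APl mirroring the COCO summary."""
    aps = [reference_ap(detections, gts, t, max_dets=max_dets) for t in IOU_THRS]
    area_m = (32.0**2, 96.0**2)
    area_l = (96.0**2, 1e10)
    ap_m = [reference_ap(detections, gts, t, area_m, max_dets) for t in IOU_THRS]
    ap_l = [reference_ap(detections, gts, t, area_l, max_dets) for t in IOU_THRS]

    def avg(vals):
        vals = [v for v in vals if v != -1.0]
        return float(np.mean(vals)) if vals else -1.0

    return {
        "mAP": float(np.mean(aps)),
        "AP50": aps[0],
        "AP75": aps[5],
        "APm": avg(ap_m) if any(v != -1 for v in ap_m) else -1.0,
        "APl": avg(ap_l) if any(v != -1 for v in ap_l) else -1.0,
    }
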