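"""Anchor-free one-stage detection head, target assignment and losses.

Feature maps from the backbone (strides 8/16/32) feed a feature pyramid
(P3..P7, strides 8..128).  Every pyramid location is a training sample: a
location is positive if it falls inside a ground-truth box and the largest of
its ltrb distances lies within the level's regression range; ambiguity between
overlapping boxes resolves to the smallest-area box.  The loss is

    total = L_cls / N_pos + lambda1 * L_centerness / N_pos
                          + lambda2 * L_reg / N_pos

with focal classification loss over all locations, binary cross-entropy on the
centerness of positives, and a selectable IoU-family regression loss (plain
IoU, GIoU, CIoU or the aspect-weighted center-distance WIoU) over positives
between the decoded predicted box and its assigned ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import MWSwinBackbone, VariantSpec, count_backbone_parameters, get_variant
from .boxes import iou_matrix
from .nn import Tensor

__all__ = [
    "FPN_STRIDES",
    "REGRESSION_RANGES",
    "DetectorConfig",
    "LossConfig",
    "LossBreakdown",
    "Detection",
    "Assignment",
    "FeaturePyramid",
    "FCOSHead",
    "WheatFormerDetector",
    "generate_locations",
    "assign_targets",
    "nms",
    "count_detector_parameters",
    "count_parameters",
]

FPN_STRIDES = (8, 16, 32, 64, 128)

# per-level (lo, hi) bounds on max(l, t, r, b) for positive assignment
REGRESSION_RANGES = ((0, 64), (64, 128), (128, 256), (256, 512), (512, math.inf))

REG_LOSS_VARIANTS = ("iou", "giou", "ciou", "wiou")


@dataclass(frozen=True)
class LossConfig:
    reg_loss: str = "wiou"
    lambda1: float = 1.0
    lambda2: float = 1.0
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    wiou_normalize_distance: bool = False

    def __post_init__(self):
        if self.reg_loss not in REG_LOSS_VARIANTS:
            raise ValueError(
                f"unknown regression loss {self.reg_loss!r}; "
                f"choose from {REG_LOSS_VARIANTS}"
            )


@dataclass(frozen=True)
class DetectorConfig:
    num_classes: int = 1
    fpn_channels: int = 256
    tower_convs: int = 4
    score_threshold: float = 0.05
    nms_threshold: float = 0.6
    pre_nms_topk: int = 1000
    max_detections: int = 100


@dataclass
class LossBreakdown:
    """Per-component losses, each already divided by N_pos."""

    cls: float
    centerness: float
    reg: float
    total_tensor: Tensor
    n_pos: int

    @property
    def total(self) -> float:
        return float(self.total_tensor.data)


@dataclass(frozen=True)
class Detection:
    box: np.ndarray  # [x0, y0, x1, y1]
    score: float
    class_id: int = 1


@dataclass
class Assignment:
    labels: np.ndarray        # (N,) int, -1 negative else gt class index (0-based)
    ltrb: np.ndarray          # (N, 4) regression targets, valid where positive
    centerness: np.ndarray    # (N,) centerness targets, valid where positive
    gt_boxes: np.ndarray      # (N, 4) assigned gt box per positive location
    n_pos: int                # positive count (before the >=1 normalization clamp)

    @property
    def positive_mask(self) -> np.ndarray:
        return self.labels >= 0


class FeaturePyramid(nn.Module):
    """Lateral 1x1 projections + top-down sums + 3x3 smoothing (P3..P5);
    P6/P7 by stride-2 3x3 convolutions from P5."""

    def __init__(self, in_channels, out_channels: int, rng: np.random.Generator):
        if len(in_channels) != 3:
            raise ValueError("expected three input maps (strides 8/16/32)")
        self.laterals = [nn.Linear(c, out_channels, rng) for c in in_channels]
        self.smooth = [nn.Conv2d(out_channels, out_channels, 3, rng) for _ in range(3)]
        self.p6 = nn.Conv2d(out_channels, out_channels, 3, rng, stride=2)
        self.p7 = nn.Conv2d(out_channels, out_channels, 3, rng, stride=2)

    def forward(self, feats) -> list[Tensor]:
        c3, c4, c5 = [lat(f) for lat, f in zip(self.laterals, feats)]
        m5 = c5
        m4 = c4 + nn.upsample2x(m5)[:, : c4.shape[1], : c4.shape[2], :]
        m3 = c3 + nn.upsample2x(m4)[:, : c3.shape[1], : c3.shape[2], :]
        p3, p4, p5 = (s(m) for s, m in zip(self.smooth, (m3, m4, m5)))
        p6 = self.p6(p5)
        p7 = self.p7(nn.relu(p6))
        return [p3, p4, p5, p6, p7]


class FCOSHead(nn.Module):
    """Shared classification/regression towers over all pyramid levels.

    Regression outputs are decoded as exp(scale_level * x) * stride, keeping
    the four ltrb distances positive.
    """

    def __init__(self, channels: int, num_classes: int, tower_convs: int,
                 rng: np.random.Generator, prior_prob: float = 0.01):
        self.cls_tower = [nn.Conv2d(channels, channels, 3, rng) for _ in range(tower_convs)]
        self.reg_tower = [nn.Conv2d(channels, channels, 3, rng) for _ in range(tower_convs)]
        self.cls_pred = nn.Conv2d(channels, num_classes, 3, rng)
        self.ctr_pred = nn.Conv2d(channels, 1, 3, rng)
        self.reg_pred = nn.Conv2d(channels, 4, 3, rng)
        self.scales = nn.Parameter(np.ones(len(FPN_STRIDES)))
        # bias init so that initial foreground probability ~= prior_prob
        self.cls_pred.bias.data[:] = -math.log((1 - prior_prob) / prior_prob)

    def forward(self, pyramid) -> list[dict]:
        out = []
        for level, p in enumerate(pyramid):
            ct = p
            for conv in self.cls_tower:
                ct = nn.relu(conv(ct))
            rt = p
            for conv in self.reg_tower:
                rt = nn.relu(conv(rt))
            stride = FPN_STRIDES[level]
            scale = self.scales[level]
            reg_raw = self.reg_pred(rt)
            ltrb = nn.exp(reg_raw * scale) * float(stride)
            out.append(
                {
                    "cls_logits": self.cls_pred(ct),
                    "ctr_logits": self.ctr_pred(rt),
                    "ltrb": ltrb,
                    "stride": stride,
                }
            )
        return out


def generate_locations(grid_h: int, grid_w: int, stride: int) -> np.ndarray:
    """Image-plane coordinates (x, y) of every cell center: (i s + s/2, j s + s/2)."""
    ys = (np.arange(grid_h) + 0.5) * stride
    xs = (np.arange(grid_w) + 0.5) * stride
    xx, yy = np.meshgrid(xs, ys)
    return np.stack([xx.ravel(), yy.ravel()], axis=1)


def assign_targets(locations: np.ndarray, level_ids: np.ndarray,
                   gt_boxes: np.ndarray, gt_classes: np.ndarray | None = None,
                   ranges=REGRESSION_RANGES) -> Assignment:
    """Per-location training targets.

    ``locations`` is (N, 2); ``level_ids`` (N,) indexes into ``ranges``;
    ``gt_boxes`` is (M, 4) [x0, y0, x1, y1].  With no ground truth every
    location is negative.
    """
    n = len(locations)
    labels = np.full(n, -1, dtype=np.int64)
    ltrb = np.zeros((n, 4))
    ctr = np.zeros(n)
    assigned = np.zeros((n, 4))
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64).reshape(-1, 4)
    m = len(gt_boxes)
    if m == 0:
        return Assignment(labels, ltrb, ctr, assigned, 0)
    if gt_classes is None:
        gt_classes = np.zeros(m, dtype=np.int64)

    xs, ys = locations[:, 0:1], locations[:, 1:2]
    l = xs - gt_boxes[None, :, 0]
    t = ys - gt_boxes[None, :, 1]
    r = gt_boxes[None, :, 2] - xs
    b = gt_boxes[None, :, 3] - ys
    reg = np.stack([l, t, r, b], axis=-1)  # (N, M, 4)
    inside = reg.min(axis=-1) > 0
    max_reg = reg.max(axis=-1)
    lo = np.array([ranges[i][0] for i in level_ids])[:, None]
    hi = np.array([ranges[i][1] for i in level_ids])[:, None]
    in_range = (max_reg >= lo) & (max_reg < hi)
    candidate = inside & in_range

    areas = (gt_boxes[:, 2] - gt_boxes[:, 0]) * (gt_boxes[:, 3] - gt_boxes[:, 1])
    area_grid = np.where(candidate, areas[None, :], np.inf)
    best = area_grid.argmin(axis=1)
    pos = candidate[np.arange(n), best]

    idx = np.flatnonzero(pos)
    labels[idx] = gt_classes[best[idx]]
    ltrb[idx] = reg[idx, best[idx]]
    assigned[idx] = gt_boxes[best[idx]]
    lt = ltrb[idx]
    lr = np.minimum(lt[:, 0], lt[:, 2]) / np.maximum(lt[:, 0], lt[:, 2])
    tb = np.minimum(lt[:, 1], lt[:, 3]) / np.maximum(lt[:, 1], lt[:, 3])
    ctr[idx] = np.sqrt(lr * tb)
    return Assignment(labels, ltrb, ctr, assigned, int(pos.sum()))


# ---------------------------------------------------------------------------
# Differentiable regression losses (Tensor path; the scalar reference lives in
# wheatformer.boxes and the two are cross-checked in the tests)
# ---------------------------------------------------------------------------

def _decoded_iou_terms(pred_boxes: Tensor, gt: np.ndarray):
    px0, py0 = pred_boxes[:, 0], pred_boxes[:, 1]
    px1, py1 = pred_boxes[:, 2], pred_boxes[:, 3]
    gx0, gy0, gx1, gy1 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    iw = nn.maximum(nn.minimum(px1, gx1) - nn.maximum(px0, gx0), 0.0)
    ih = nn.maximum(nn.minimum(py1, gy1) - nn.maximum(py0, gy0), 0.0)
    inter = iw * ih
    area_p = (px1 - px0) * (py1 - py0)
    area_g = (gx1 - gx0) * (gy1 - gy0)
    union = area_p + area_g - inter
    return inter / union, union


def regression_loss(pred_boxes: Tensor, gt: np.ndarray, cfg: LossConfig) -> Tensor:
    """Per-positive regression loss vector for decoded predicted boxes."""
    gt = np.asarray(gt, dtype=np.float64).reshape(-1, 4)
    iou, union = _decoded_iou_terms(pred_boxes, gt)
    if cfg.reg_loss == "iou":
        return 1.0 - iou

    px0, py0 = pred_boxes[:, 0], pred_boxes[:, 1]
    px1, py1 = pred_boxes[:, 2], pred_boxes[:, 3]
    gx0, gy0, gx1, gy1 = gt[:, 0], gt[:, 1], gt[:, 2], gt[:, 3]
    ex0 = nn.minimum(px0, gx0)
    ey0 = nn.minimum(py0, gy0)
    ex1 = nn.maximum(px1, gx1)
    ey1 = nn.maximum(py1, gy1)

    if cfg.reg_loss == "giou":
        enc = (ex1 - ex0) * (ey1 - ey0)
        return 1.0 - (iou - (enc - union) / enc)

    d2 = (0.5 * (px0 + px1) - 0.5 * (gx0 + gx1)) ** 2.0 + (
        0.5 * (py0 + py1) - 0.5 * (gy0 + gy1)
    ) ** 2.0
    v = (4.0 / math.pi**2) * (
        nn.arctan((gx1 - gx0) / (gy1 - gy0)) - nn.arctan((px1 - px0) / (py1 - py0))
    ) ** 2.0

    if cfg.reg_loss == "ciou":
        c2 = (ex1 - ex0) ** 2.0 + (ey1 - ey0) ** 2.0
        alpha = v.data / ((1.0 - iou.data) + v.data + 1e-12)  # constant under grad
        return 1.0 - iou + d2 / c2 + nn.Tensor(alpha) * v

    # wiou: aspect-consistency weight times squared center distance
    if cfg.wiou_normalize_distance:
        c2 = (ex1 - ex0) ** 2.0 + (ey1 - ey0) ** 2.0
        d2 = d2 / c2
    return 1.0 - iou + v * d2


def compute_losses(head_outputs, assignment: Assignment, locations: np.ndarray,
                   cfg: LossConfig) -> LossBreakdown:
    """Assemble the total training loss from flattened head outputs.

    ``head_outputs`` is a dict of concatenated per-location Tensors:
    ``cls_logits`` (N, num_classes), ``ctr_logits`` (N,), ``ltrb`` (N, 4).
    """
    cls_logits = head_outputs["cls_logits"]
    ctr_logits = head_outputs["ctr_logits"]
    ltrb = head_outputs["ltrb"]
    n, num_classes = cls_logits.shape
    n_pos_norm = max(assignment.n_pos, 1)

    onehot = np.zeros((n, num_classes))
    pos = assignment.positive_mask
    idx = np.flatnonzero(pos)
    if len(idx):
        onehot[idx, assignment.labels[idx]] = 1.0
    cls_loss = nn.sigmoid_focal_loss(
        cls_logits, onehot, alpha=cfg.focal_alpha, gamma=cfg.focal_gamma
    ).sum() * (1.0 / n_pos_norm)

    if len(idx):
        ctr_loss = nn.binary_cross_entropy_with_logits(
            ctr_logits[idx], assignment.centerness[idx]
        ).sum() * (1.0 / n_pos_norm)
        loc = locations[idx]
        lt = ltrb[idx]
        pred_boxes = nn.concatenate(
            [
                (loc[:, 0] - lt[:, 0]).reshape(-1, 1),
                (loc[:, 1] - lt[:, 1]).reshape(-1, 1),
                (loc[:, 0] + lt[:, 2]).reshape(-1, 1),
                (loc[:, 1] + lt[:, 3]).reshape(-1, 1),
            ],
            axis=1,
        )
        reg_loss = regression_loss(
            pred_boxes, assignment.gt_boxes[idx], cfg
        ).sum() * (1.0 / n_pos_norm)
    else:
        ctr_loss = nn.Tensor(0.0)
        reg_loss = nn.Tensor(0.0)

    total = cls_loss + cfg.lambda1 * ctr_loss + cfg.lambda2 * reg_loss
    return LossBreakdown(
        cls=float(cls_loss.data),
        centerness=float(ctr_loss.data),
        reg=float(reg_loss.data),
        total_tensor=total,
        n_pos=assignment.n_pos,
    )


def nms(boxes: np.ndarray, scores: np.ndarray, threshold: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices in score order."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    while len(order):
        i = order[0]
        keep.append(i)
        if len(order) == 1:
            break
        rest = order[1:]
        ious = iou_matrix(boxes[i], boxes[rest])[0]
        order = rest[ious <= threshold]
    return np.asarray(keep, dtype=np.int64)


class WheatFormerDetector(nn.Module):
    """Backbone + feature pyramid + anchor-free head, end to end."""

    def __init__(self, variant: VariantSpec | str, rng: np.random.Generator | int = 0,
                 config: DetectorConfig = DetectorConfig(),
                 loss_config: LossConfig = LossConfig()):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        if isinstance(variant, str):
            variant = get_variant(variant)
        self.variant = variant
        self.config = config
        self.loss_config = loss_config
        self.backbone = MWSwinBackbone(variant, rng)
        in_channels = [s.channels for s in variant.stages[1:]]
        self.fpn = FeaturePyramid(in_channels, config.fpn_channels, rng)
        self.head = FCOSHead(config.fpn_channels, config.num_classes,
                             config.tower_convs, rng)

    def forward(self, image: np.ndarray) -> list[dict]:
        feats = self.backbone(image)
        pyramid = self.fpn(feats[1:])  # strides 8, 16, 32
        return self.head(pyramid)

    # -- flattening helpers ------------------------------------------------
    @staticmethod
    def flatten_outputs(level_outputs) -> tuple[dict, np.ndarray, np.ndarray]:
        """Concatenate per-level maps to per-location rows (batch size 1)."""
        cls_list, ctr_list, ltrb_list, locs, level_ids = [], [], [], [], []
        for lvl, out in enumerate(level_outputs):
            b, h, w, nc = out["cls_logits"].shape
            if b != 1:
                raise ValueError("flatten_outputs expects batch size 1")
            cls_list.append(out["cls_logits"].reshape(h * w, nc))
            ctr_list.append(out["ctr_logits"].reshape(h * w))
            ltrb_list.append(out["ltrb"].reshape(h * w, 4))
            locs.append(generate_locations(h, w, out["stride"]))
            level_ids.append(np.full(h * w, lvl, dtype=np.int64))
        flat = {
            "cls_logits": nn.concatenate(cls_list, axis=0),
            "ctr_logits": nn.concatenate(ctr_list, axis=0),
            "ltrb": nn.concatenate(ltrb_list, axis=0),
        }
        return flat, np.concatenate(locs), np.concatenate(level_ids)

    def loss(self, image: np.ndarray, gt_boxes: np.ndarray,
             gt_classes: np.ndarray | None = None) -> LossBreakdown:
        outputs = self.forward(image)
        flat, locations, level_ids = self.flatten_outputs(outputs)
        assignment = assign_targets(locations, level_ids, gt_boxes, gt_classes)
        return compute_losses(flat, assignment, locations, self.loss_config)

    def detect(self, image: np.ndarray) -> list[Detection]:
        cfg = self.config
        image = np.asarray(image, dtype=np.float64)
        h_img, w_img = image.shape[-3], image.shape[-2]
        with nn.no_grad():
            outputs = self.forward(image)
        all_boxes, all_scores, all_classes = [], [], []
        for out in outputs:
            b, h, w, nc = out["cls_logits"].shape
            cls = 1.0 / (1.0 + np.exp(-out["cls_logits"].data.reshape(h * w, nc)))
            ctr = 1.0 / (1.0 + np.exp(-out["ctr_logits"].data.reshape(h * w, 1)))
            scores = cls * ctr
            ltrb = out["ltrb"].data.reshape(h * w, 4)
            locs = generate_locations(h, w, out["stride"])
            flat_scores = scores.ravel()
            keep = np.flatnonzero(flat_scores > cfg.score_threshold)
            if len(keep) > cfg.pre_nms_topk:
                keep = keep[np.argsort(-flat_scores[keep], kind="stable")[: cfg.pre_nms_topk]]
            loc_idx, cls_idx = np.divmod(keep, nc)
            boxes = np.stack(
                [
                    locs[loc_idx, 0] - ltrb[loc_idx, 0],
                    locs[loc_idx, 1] - ltrb[loc_idx, 1],
                    locs[loc_idx, 0] + ltrb[loc_idx, 2],
                    locs[loc_idx, 1] + ltrb[loc_idx, 3],
                ],
                axis=1,
            )
            boxes[:, 0::2] = boxes[:, 0::2].clip(0, w_img)
            boxes[:, 1::2] = boxes[:, 1::2].clip(0, h_img)
            all_boxes.append(boxes)
            all_scores.append(flat_scores[keep])
            all_classes.append(cls_idx)
        boxes = np.concatenate(all_boxes) if all_boxes else np.zeros((0, 4))
        scores = np.concatenate(all_scores) if all_scores else np.zeros(0)
        classes = np.concatenate(all_classes) if all_classes else np.zeros(0, dtype=np.int64)

        detections: list[Detection] = []
        for c in np.unique(classes):
            sel = np.flatnonzero(classes == c)
            valid = sel[
                (boxes[sel, 2] > boxes[sel, 0]) & (boxes[sel, 3] > boxes[sel, 1])
            ]
            if not len(valid):
                continue
            kept = valid[nms(boxes[valid], scores[valid], cfg.nms_threshold)]
            for i in kept:
                detections.append(
                    Detection(box=boxes[i].copy(), score=float(scores[i]),
                              class_id=int(c) + 1)
                )
        detections.sort(key=lambda d: -d.score)
        return detections[: cfg.max_detections]


# ---------------------------------------------------------------------------
# Parameter counting (backbone + detector)
# ---------------------------------------------------------------------------

def count_detector_parameters(variant: VariantSpec,
                              config: DetectorConfig = DetectorConfig()) -> int:
    """Closed-form count of FPN + head parameters."""
    p = config.fpn_channels
    total = 0
    for c in [s.channels for s in variant.stages[1:]]:
        total += c * p + p                      # lateral
    total += 3 * (9 * p * p + p)                # smoothing convs
    total += 2 * (9 * p * p + p)                # p6, p7
    total += 2 * config.tower_convs * (9 * p * p + p)  # cls/reg towers
    total += 9 * p * config.num_classes + config.num_classes  # cls pred
    total += 9 * p * 1 + 1                      # centerness pred
    total += 9 * p * 4 + 4                      # reg pred
    total += len(FPN_STRIDES)                   # per-level scales
    return total


def count_parameters(variant: VariantSpec | str, include_detector: bool = True,
                     config: DetectorConfig = DetectorConfig()) -> int:
    """Closed-form learnable-parameter count of the full model.

    Equals ``WheatFormerDetector(variant).num_parameters()`` exactly (or the
    bare backbone count when ``include_detector`` is false).
    """
    if isinstance(variant, str):
        variant = get_variant(variant)
    total = count_backbone_parameters(variant)
    if include_detector:
        total += count_detector_parameters(variant, config)
    return total
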