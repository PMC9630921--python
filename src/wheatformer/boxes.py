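"""Axis-aligned box arithmetic, IoU-family losses and ltrb distance targets.

Coordinates are continuous, origin at the top-left, x rightward, y downward.
A box is the continuous rectangle [x0, x1] x [y0, y1] with area
(x1 - x0) * (y1 - y0); no +1 pixel correction is applied anywhere.

The WIoU loss couples an aspect-ratio consistency weight with the *raw*
squared center distance: loss = 1 - IoU + psi * ||c_pred - c_gt||^2.  Because
psi multiplies (rather than adds to) the distance term, the penalty vanishes
entirely whenever the two aspect ratios are equal — this is a property of the
formula as published and is asserted in the tests.  An optional
``normalize_distance`` mode divides the distance term by the squared diagonal
of the smallest enclosing box for training stability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Box",
    "Location",
    "RegressionTarget",
    "WIoUDecomposition",
    "GeometryError",
    "AssignmentError",
    "iou",
    "giou",
    "ciou_loss",
    "aspect_penalty",
    "wiou_loss",
    "encode_ltrb",
    "decode_ltrb",
    "centerness",
    "iou_matrix",
]

VALID_STRIDES = (8, 16, 32, 64, 128)


class GeometryError(ValueError):
    """Raised for degenerate (zero/negative area) boxes."""


class AssignmentError(ValueError):
    """Raised when a location lies outside the box it is encoded against."""


@dataclass(frozen=True)
class Box:
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def w(self) -> float:
        return self.x1 - self.x0

    @property
    def h(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.w * self.h

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "Box":
        return cls(x, y, x + w, y + h)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.w, self.h)

    def contains(self, x: float, y: float) -> bool:
        """Inclusive interior test (edges count as inside)."""
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass(frozen=True)
class Location:
    x: float
    y: float
    stride: int = 8

    def __post_init__(self):
        if self.stride not in VALID_STRIDES:
            raise ValueError(f"stride must be one of {VALID_STRIDES}, got {self.stride}")


@dataclass(frozen=True)
class RegressionTarget:
    l: float
    t: float
    r: float
    b: float


@dataclass(frozen=True)
class WIoUDecomposition:
    iou: float
    psi: float
    center_dist_sq: float
    loss: float


def _check(box: Box, name: str = "box") -> None:
    if not (box.x1 > box.x0 and box.y1 > box.y0):
        raise GeometryError(f"{name} is degenerate: {box}")


def iou(a: Box, b: Box) -> float:
    _check(a, "a")
    _check(b, "b")
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = a.area + b.area - inter
    return inter / union


def giou(a: Box, b: Box) -> float:
    _check(a, "a")
    _check(b, "b")
    enclosing = Box(min(a.x0, b.x0), min(a.y0, b.y0), max(a.x1, b.x1), max(a.y1, b.y1))
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    inter = max(iw, 0.0) * max(ih, 0.0)
    union = a.area + b.area - inter
    return inter / union - (enclosing.area - union) / enclosing.area


def aspect_penalty(pred: Box, gt: Box) -> float:
    """psi = 4/pi^2 * (arctan(w_gt/h_gt) - arctan(w_pred/h_pred))^2."""
    _check(pred, "pred")
    _check(gt, "gt")
    return (4.0 / math.pi**2) * (
        math.atan(gt.w / gt.h) - math.atan(pred.w / pred.h)
    ) ** 2


def ciou_loss(pred: Box, gt: Box) -> float:
    """Complete-IoU loss: 1 - IoU + d^2/c^2 + alpha * v.

    v is the arctan aspect term (identical to :func:`aspect_penalty`) and
    alpha = v / ((1 - IoU) + v), treated as a constant during differentiation.
    """
    _check(pred, "pred")
    _check(gt, "gt")
    i = iou(pred, gt)
    cx_p, cy_p = pred.center
    cx_g, cy_g = gt.center
    d2 = (cx_p - cx_g) ** 2 + (cy_p - cy_g) ** 2
    c2 = (max(pred.x1, gt.x1) - min(pred.x0, gt.x0)) ** 2 + (
        max(pred.y1, gt.y1) - min(pred.y0, gt.y0)
    ) ** 2
    v = aspect_penalty(pred, gt)
    alpha = 0.0 if v == 0.0 else v / ((1.0 - i) + v)
    return 1.0 - i + d2 / c2 + alpha * v


def wiou_loss(pred: Box, gt: Box, normalize_distance: bool = False) -> WIoUDecomposition:
    """Aspect-weighted center-distance IoU loss (see module docstring)."""
    _check(pred, "pred")
    _check(gt, "gt")
    i = iou(pred, gt)
    psi = aspect_penalty(pred, gt)
    cx_p, cy_p = pred.center
    cx_g, cy_g = gt.center
    d2 = (cx_p - cx_g) ** 2 + (cy_p - cy_g) ** 2
    dist_term = d2
    if normalize_distance:
        c2 = (max(pred.x1, gt.x1) - min(pred.x0, gt.x0)) ** 2 + (
            max(pred.y1, gt.y1) - min(pred.y0, gt.y0)
        ) ** 2
        dist_term = d2 / c2
    loss = 1.0 - i + psi * dist_term
    return WIoUDecomposition(iou=i, psi=psi, center_dist_sq=d2, loss=loss)


def encode_ltrb(loc: Location, box: Box) -> RegressionTarget:
    """Distances from a location to the four box edges.

    Boundary locations (a zero component) are treated as inside; positivity
    filtering is the assigner's responsibility.
    """
    _check(box)
    l = loc.x - box.x0
    t = loc.y - box.y0
    r = box.x1 - loc.x
    b = box.y1 - loc.y
    if min(l, t, r, b) < 0:
        raise AssignmentError(f"location ({loc.x}, {loc.y}) outside box {box}")
    return RegressionTarget(l, t, r, b)


def decode_ltrb(loc: Location, target: RegressionTarget) -> Box:
    if min(target.l, target.t, target.r, target.b) < 0:
        raise ValueError(f"negative ltrb component: {target}")
    return Box(loc.x - target.l, loc.y - target.t, loc.x + target.r, loc.y + target.b)


def centerness(target: RegressionTarget) -> float:
    """sqrt(min(l,r)/max(l,r) * min(t,b)/max(t,b)); 1 at the center, 0 on edges."""
    lr_max = max(target.l, target.r)
    tb_max = max(target.t, target.b)
    if lr_max <= 0 or tb_max <= 0:
        return 0.0
    val = (min(target.l, target.r) / lr_max) * (min(target.t, target.b) / tb_max)
    return math.sqrt(val)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of two (N, 4) / (M, 4) arrays of [x0, y0, x1, y1] boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    x0 = np.maximum(a[:, None, 0], b[None, :, 0])
    y0 = np.maximum(a[:, None, 1], b[None, :, 1])
    x1 = np.minimum(a[:, None, 2], b[None, :, 2])
    y1 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(x1 - x0, 0, None) * np.clip(y1 - y0, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out
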