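"""Seeded synthetic wheat-scene generator with exact ground-truth boxes.

Scenes emulate dense field imagery: a textured background (low-frequency
noise plus a directional illumination gradient) with 20-80 elongated, striped,
rotated spike-like ellipses per image, drawn back to front so later spikes
occlude earlier ones.  Every spike's annotation is the exact axis-aligned
bounding box of its rendered mask *before* occlusion (amodal extent), so the
ground truth is tight by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "SynthSceneConfig",
    "AnnotatedImage",
    "DatasetManifest",
    "GenerationError",
    "generate_scene",
    "generate_dataset",
    "split_dataset",
]


class GenerationError(RuntimeError):
    """Raised when a spike cannot be placed within bounds."""


@dataclass(frozen=True)
class SynthSceneConfig:
    image_size: tuple = (256, 256)           # (H, W)
    spike_count: tuple = (20, 80)            # inclusive range
    spike_length: tuple = (28.0, 64.0)       # major-axis length, pixels
    spike_width: tuple = (8.0, 16.0)         # minor-axis width, pixels
    illumination_strength: float = 0.35      # gradient amplitude in [0, 1]
    background_scale: int = 16               # texture cell size, pixels
    stripe_period: float = 6.0               # awn-stripe spacing along the axis
    max_place_tries: int = 50

    def __post_init__(self):
        if self.spike_count[0] < 1 or self.spike_count[1] < self.spike_count[0]:
            raise ValueError(f"invalid spike count range {self.spike_count}")


@dataclass
class AnnotatedImage:
    image: np.ndarray               # (H, W, 3) uint8
    boxes: np.ndarray               # (N, 4) float [x0, y0, x1, y1]
    image_id: int
    metadata: dict = field(default_factory=dict)


@dataclass
class DatasetManifest:
    train: list
    validation: list

    def to_json(self) -> str:
        return json.dumps({"train": self.train, "validation": self.validation}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        return cls(train=d["train"], validation=d["validation"])


def _background(rng: np.random.Generator, h: int, w: int,
                cfg: SynthSceneConfig) -> np.ndarray:
    """Low-frequency noise field plus a random-direction illumination ramp."""
    cs = cfg.background_scale
    gh, gw = h // cs + 2, w // cs + 2
    coarse = rng.uniform(0.25, 0.55, size=(gh, gw, 3))
    # bilinear upsample of the coarse grid
    yy = np.linspace(0, gh - 1.001, h)
    xx = np.linspace(0, gw - 1.001, w)
    y0 = yy.astype(int)
    x0 = xx.astype(int)
    fy = (yy - y0)[:, None, None]
    fx = (xx - x0)[None, :, None]
    bg = (
        coarse[y0][:, x0] * (1 - fy) * (1 - fx)
        + coarse[y0 + 1][:, x0] * fy * (1 - fx)
        + coarse[y0][:, x0 + 1] * (1 - fy) * fx
        + coarse[y0 + 1][:, x0 + 1] * fy * fx
    )
    bg[..., 1] *= 1.15  # greenish cast
    theta = rng.uniform(0, 2 * np.pi)
    ys, xs = np.mgrid[0:h, 0:w]
    ramp = (np.cos(theta) * xs / w + np.sin(theta) * ys / h)
    ramp = (ramp - ramp.min()) / max(np.ptp(ramp), 1e-9)
    bg *= (1.0 - cfg.illumination_strength / 2 + cfg.illumination_strength * ramp)[..., None]
    return np.clip(bg, 0, 1)


def _spike_mask_and_color(rng: np.random.Generator, h: int, w: int,
                          cfg: SynthSceneConfig):
    """Sample one spike; returns (mask, color image patch, tight box)."""
    length = rng.uniform(*cfg.spike_length)
    width = rng.uniform(*cfg.spike_width)
    angle = rng.uniform(0, np.pi)
    a, b = length / 2.0, width / 2.0
    # rotated-ellipse half extents
    ex = np.sqrt((a * np.cos(angle)) ** 2 + (b * np.sin(angle)) ** 2)
    ey = np.sqrt((a * np.sin(angle)) ** 2 + (b * np.cos(angle)) ** 2)
    if 2 * ex + 2 >= w or 2 * ey + 2 >= h:
        return None  # spike cannot fit at all with this draw
    cx = rng.uniform(ex + 1, w - ex - 1)
    cy = rng.uniform(ey + 1, h - ey - 1)

    x_lo = max(int(np.floor(cx - ex)) - 1, 0)
    x_hi = min(int(np.ceil(cx + ex)) + 2, w)
    y_lo = max(int(np.floor(cy - ey)) - 1, 0)
    y_hi = min(int(np.ceil(cy + ey)) + 2, h)
    ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
    # pixel centers at integer coordinates
    dx = xs - cx
    dy = ys - cy
    u = dx * np.cos(angle) + dy * np.sin(angle)    # along major axis
    v = -dx * np.sin(angle) + dy * np.cos(angle)   # across
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        return None

    base = np.array([0.78, 0.70, 0.35]) * rng.uniform(0.8, 1.1)
    stripes = 0.78 + 0.22 * np.cos(2 * np.pi * u / cfg.stripe_period)
    color = np.clip(base[None, None, :] * stripes[..., None], 0, 1)

    cols = np.flatnonzero(mask.any(axis=0))
    rows = np.flatnonzero(mask.any(axis=1))
    # pixel (r, c) covers the continuous square [c, c+1) x [r, r+1) — the box
    # is the exact extent of the rendered mask
    box = np.array(
        [x_lo + cols[0], y_lo + rows[0], x_lo + cols[-1] + 1, y_lo + rows[-1] + 1],
        dtype=np.float64,
    )
    return mask, color, (slice(y_lo, y_hi), slice(x_lo, x_hi)), box


def generate_scene(cfg: SynthSceneConfig, seed: int, image_id: int = 0) -> AnnotatedImage:
    """Render one scene deterministically from (cfg, seed)."""
    rng = np.random.default_rng(seed)
    h, w = cfg.image_size
    img = _background(rng, h, w, cfg)
    n_spikes = int(rng.integers(cfg.spike_count[0], cfg.spike_count[1] + 1))
    boxes = []
    for _ in range(n_spikes):
        placed = None
        for _try in range(cfg.max_place_tries):
            placed = _spike_mask_and_color(rng, h, w, cfg)
            if placed is not None:
                break
        if placed is None:
            raise GenerationError(
                f"could not place spike within bounds after {cfg.max_place_tries} tries"
            )
        mask, color, window, box = placed
        img[window][mask] = color[mask]
        boxes.append(box)
    image8 = (img * 255.0 + 0.5).astype(np.uint8)
    return AnnotatedImage(
        image=image8,
        boxes=np.asarray(boxes, dtype=np.float64).reshape(-1, 4),
        image_id=image_id,
        metadata={"source": "synthetic", "seed": int(seed)},
    )


def generate_dataset(cfg: SynthSceneConfig, n_images: int, out_dir,
                     master_seed: int = 0) -> DatasetManifest:
    """Write a dataset: PNG images, per-image VOC XML, one COCO JSON, manifest.

    Per-image seeds are spawned from the master seed, so regeneration with the
    same master seed reproduces every file exactly.
    """
    from .annotations import write_coco_json, write_labelimg_xml

    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(master_seed).generate_state(n_images)
    records = []
    for i in range(n_images):
        rec = generate_scene(cfg, int(seeds[i]), image_id=i)
        name = f"scene_{i:05d}"
        img_path = out_dir / "images" / f"{name}.png"
        _save_png(rec.image, img_path)
        write_labelimg_xml(rec, out_dir / "annotations" / f"{name}.xml",
                           filename=f"{name}.png")
        records.append(rec)
        rec.metadata["file_name"] = f"{name}.png"
    write_coco_json(records, out_dir / "annotations" / "coco.json")
    entries = [
        {"image_id": r.image_id, "file_name": r.metadata["file_name"],
         "n_boxes": int(len(r.boxes)), "seed": r.metadata["seed"]}
        for r in records
    ]
    manifest = DatasetManifest(train=entries, validation=[])
    (out_dir / "manifest.json").write_text(manifest.to_json())
    (out_dir / "config.json").write_text(json.dumps(asdict(cfg), default=list, indent=1))
    return manifest


def _save_png(image: np.ndarray, path) -> None:
    from PIL import Image

    Image.fromarray(image, mode="RGB").save(path)


def split_dataset(manifest: DatasetManifest, ratio: float, seed: int,
                  by_source: bool = False) -> DatasetManifest:
    """Seeded shuffle split: floor(ratio * n) records to train, rest validation.

    With ``by_source`` the split is applied independently within each record
    ``source`` group (stratified per data source).
    """
    if not (0 < ratio < 1):
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    records = list(manifest.train) + list(manifest.validation)
    if not records:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(seed)
    groups: dict[str, list] = {}
    if by_source:
        for r in records:
            groups.setdefault(r.get("source", ""), []).append(r)
    else:
        groups[""] = records
    train, val = [], []
    for key in sorted(groups):
        recs = groups[key]
        order = rng.permutation(len(recs))
        n_train = int(ratio * len(recs))
        train.extend(recs[i] for i in order[:n_train])
        val.extend(recs[i] for i in order[n_train:])
    return DatasetManifest(train=train, validation=val)
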