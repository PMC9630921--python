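"""Training/evaluation/prediction loops wiring backbone + detector + losses.

Each command is a plain function (the CLI wraps them); all randomness flows
from the run config's master seed, so reruns are reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import nn
from .annotations import detections_to_coco_results, read_coco_json
from .backbone import VariantSpec, pad_image
from .config import RunConfig
from .detector import WheatFormerDetector
from .evaluation import coco_summary
from .synth import SynthSceneConfig, generate_dataset, split_dataset, DatasetManifest

log = logging.getLogger("wheatformer")

__all__ = [
    "save_checkpoint",
    "load_checkpoint",
    "run_synth",
    "run_train",
    "run_eval",
    "run_predict",
]

METRICS_SCHEMA_VERSION = 1


def save_checkpoint(path, model: WheatFormerDetector, optimizer=None,
                    iteration: int = 0) -> None:
    """Serialize weights (npz) with the variant spec embedded."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    if optimizer is not None:
        state = optimizer.state_dict()
        arrays["opt/t"] = np.array(state["t"])
        for i, m in enumerate(state["m"]):
            arrays[f"opt/m/{i}"] = m
        for i, v in enumerate(state["v"]):
            arrays[f"opt/v/{i}"] = v
    arrays["meta/variant"] = np.array(model.variant.to_json())
    arrays["meta/iteration"] = np.array(iteration)
    arrays["meta/fpn_channels"] = np.array(model.config.fpn_channels)
    arrays["meta/tower_convs"] = np.array(model.config.tower_convs)
    arrays["meta/num_classes"] = np.array(model.config.num_classes)
    np.savez(path, **arrays)


def load_checkpoint(path, config=None, loss_config=None):
    """Rebuild a detector (and optimizer state, iteration) from a checkpoint."""
    from .detector import DetectorConfig, LossConfig

    with np.load(path, allow_pickle=False) as data:
        variant = VariantSpec.from_json(str(data["meta/variant"]))
        if config is None:
            config = DetectorConfig(
                num_classes=int(data["meta/num_classes"]),
                fpn_channels=int(data["meta/fpn_channels"]),
                tower_convs=int(data["meta/tower_convs"]),
            )
        elif config.fpn_channels != int(data["meta/fpn_channels"]) or \
                config.tower_convs != int(data["meta/tower_convs"]):
            raise ValueError("checkpoint/config mismatch in detector head settings")
        model = WheatFormerDetector(variant, rng=0, config=config,
                                    loss_config=loss_config or LossConfig())
        params = {k[len("param/"):]: data[k] for k in data.files
                  if k.startswith("param/")}
        model.load_state_dict(params)
        opt_state = None
        if "opt/t" in data.files:
            n = len(model.parameters())
            opt_state = {
                "t": int(data["opt/t"]),
                "m": [data[f"opt/m/{i}"] for i in range(n)],
                "v": [data[f"opt/v/{i}"] for i in range(n)],
            }
        iteration = int(data["meta/iteration"])
    return model, opt_state, iteration


def _scene_config(cfg: RunConfig) -> SynthSceneConfig:
    length = cfg.spike_length or (max(10.0, cfg.image_size / 5),
                                  max(16.0, cfg.image_size / 3))
    width = cfg.spike_width or (4.0, max(6.0, cfg.image_size / 16))
    return SynthSceneConfig(
        image_size=(cfg.image_size, cfg.image_size),
        spike_count=tuple(cfg.spike_count),
        spike_length=tuple(length),
        spike_width=tuple(width),
    )


def run_synth(cfg: RunConfig) -> Path:
    """Generate the synthetic dataset, split it 8:2 and write a manifest."""
    out = Path(cfg.data_dir)
    manifest = generate_dataset(_scene_config(cfg), cfg.n_images, out,
                                master_seed=cfg.seed)
    manifest = split_dataset(manifest, cfg.split_ratio, cfg.seed)
    (out / "manifest.json").write_text(manifest.to_json())
    log.info("wrote %d train / %d validation records to %s",
             len(manifest.train), len(manifest.validation), out)
    return out / "manifest.json"


def _load_records(cfg: RunConfig, subset: str):
    """Load (image, boxes, image_id) triples for a manifest subset."""
    from PIL import Image

    data_dir = Path(cfg.data_dir)
    manifest = DatasetManifest.from_json((data_dir / "manifest.json").read_text())
    entries = getattr(manifest, subset)
    coco = read_coco_json(data_dir / "annotations" / "coco.json")
    records = []
    for e in entries:
        img = np.asarray(Image.open(data_dir / "images" / e["file_name"]).convert("RGB"))
        records.append((img, coco["boxes"][e["image_id"]], e["image_id"]))
    return records


def _prep_image(img: np.ndarray) -> np.ndarray:
    return pad_image(np.asarray(img, dtype=np.float64) / 255.0, 32)[None]


def run_train(cfg: RunConfig, resume: str | None = None):
    """Seeded training loop; logs per-iteration losses, saves a checkpoint.

    Returns ``(checkpoint_path, loss_trace)`` where the trace is the list of
    logged per-iteration records.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = _load_records(cfg, "train")
    if not records:
        raise ValueError("training subset is empty")

    if resume:
        model, opt_state, start_iter = load_checkpoint(
            resume, config=cfg.detector_config(), loss_config=cfg.loss_configuration()
        )
    else:
        model = WheatFormerDetector(
            cfg.variant, rng=np.random.default_rng(cfg.seed),
            config=cfg.detector_config(), loss_config=cfg.loss_configuration(),
        )
        opt_state, start_iter = None, 0
    optimizer = nn.AdamW(model.parameters(), lr=cfg.learning_rate,
                         betas=tuple(cfg.adam_betas),
                         weight_decay=cfg.weight_decay)
    if opt_state is not None:
        optimizer.load_state_dict(opt_state)

    order_rng = np.random.default_rng(cfg.seed + 1)
    log_path = out_dir / "loss_log.jsonl"
    ckpt_path = out_dir / "checkpoint.npz"
    trace = []
    iteration = start_iter
    t0 = time.time()
    with log_path.open("a") as fh:
        for epoch in range(cfg.epochs):
            perm = order_rng.permutation(len(records))
            for start in range(0, len(perm), cfg.batch_size):
                if cfg.max_iterations is not None and \
                        iteration - start_iter >= cfg.max_iterations:
                    break
                batch = perm[start : start + cfg.batch_size]
                optimizer.zero_grad()
                agg = {"cls": 0.0, "centerness": 0.0, "reg": 0.0, "total": 0.0}
                inv = 1.0 / len(batch)
                for bi in batch:
                    img, boxes, _ = records[bi]
                    lb = model.loss(_prep_image(img), boxes)
                    (lb.total_tensor * inv).backward()
                    agg["cls"] += lb.cls * inv
                    agg["centerness"] += lb.centerness * inv
                    agg["reg"] += lb.reg * inv
                    agg["total"] += lb.total * inv
                if iteration < cfg.warmup_iterations:
                    optimizer.lr = cfg.learning_rate * (iteration + 1) / cfg.warmup_iterations
                elif cfg.lr_schedule == "step" and cfg.lr_step_every > 0 and \
                        iteration % cfg.lr_step_every == 0:
                    optimizer.lr *= cfg.lr_step_gamma
                else:
                    optimizer.lr = optimizer.lr
                optimizer.step()
                rec = {
                    "iteration": iteration,
                    "epoch": epoch,
                    "L_cls": agg["cls"],
                    "L_centerness": agg["centerness"],
                    "L_reg": agg["reg"],
                    "total": agg["total"],
                    "lr": optimizer.lr,
                    "seed": cfg.seed,
                }
                fh.write(json.dumps(rec) + "\n")
                trace.append(rec)
                if iteration % 20 == 0:
                    log.info(
                        "iter %d epoch %d total %.4f (cls %.4f ctr %.4f reg %.4f) %.1fs",
                        iteration, epoch, agg["total"], agg["cls"],
                        agg["centerness"], agg["reg"], time.time() - t0,
                    )
                iteration += 1
            else:
                continue
            break
    save_checkpoint(ckpt_path, model, optimizer, iteration)
    return ckpt_path, trace


def run_eval(cfg: RunConfig, checkpoint, subset: str = "validation"):
    """Detect on a manifest subset and write the metrics report JSON."""
    model, _, _ = load_checkpoint(checkpoint, config=cfg.detector_config())
    records = _load_records(cfg, subset)
    if not records:
        records = _load_records(cfg, "train")
    detections, gts = {}, {}
    for img, boxes, image_id in records:
        detections[image_id] = model.detect(_prep_image(img))
        gts[image_id] = boxes
    report = coco_summary(detections, gts)
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": METRICS_SCHEMA_VERSION, **report.to_dict()}
    (out_dir / "metrics.json").write_text(json.dumps(payload, indent=1))
    from .evaluation import ap_at_threshold

    curves = {}
    for thr in (0.5, 0.75):
        _, curve = ap_at_threshold(detections, gts, thr)
        curves[f"iou_{thr}"] = {"recall": curve.recall.tolist(),
                                "precision": curve.precision.tolist()}
    (out_dir / "pr_curves.json").write_text(json.dumps(curves))
    results = detections_to_coco_results(detections)
    (out_dir / "detections.json").write_text(json.dumps(results, indent=1))
    return report


def run_predict(cfg: RunConfig, checkpoint, image_paths, overlay: bool = False):
    """Run detection on images; returns (results, n_failed)."""
    from PIL import Image, ImageDraw

    model, _, _ = load_checkpoint(checkpoint, config=cfg.detector_config())
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_image = {}
    failed = 0
    for i, path in enumerate(image_paths):
        try:
            img = Image.open(path).convert("RGB")
        except Exception as e:  # unreadable image: skip with warning
            log.warning("skipping unreadable image %s (%s)", path, e)
            failed += 1
            continue
        arr = np.asarray(img)
        dets = model.detect(_prep_image(arr))
        per_image[i] = dets
        if overlay:
            draw = ImageDraw.Draw(img)
            for d in dets:
                draw.rectangle(list(d.box), outline=(255, 40, 40), width=2)
            img.save(out_dir / f"overlay_{Path(path).stem}.png")
    results = detections_to_coco_results(per_image)
    (out_dir / "predictions.json").write_text(json.dumps(results, indent=1))
    return results, failed
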