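"""Run configuration: YAML/JSON loadable, with training defaults of
AdamW, learning rate 1e-4, weight decay 0.05, 24 epochs."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    variant: str = "B"                 # S / B / L / tiny
    reg_loss: str = "wiou"             # iou / giou / ciou / wiou
    learning_rate: float = 1e-4
    weight_decay: float = 0.05
    epochs: int = 24
    batch_size: int = 2
    image_size: int = 128              # training crop/scene size
    seed: int = 0
    data_dir: str = "data"
    out_dir: str = "runs/default"
    max_iterations: int | None = None  # hard cap across epochs (small-scale runs)
    fpn_channels: int = 256
    tower_convs: int = 4
    num_classes: int = 1
    lr_schedule: str = "constant"      # constant / step
    lr_step_every: int = 0             # iterations between decays (step mode)
    lr_step_gamma: float = 0.1
    warmup_iterations: int = 0         # linear LR ramp at the start
    adam_betas: tuple = (0.9, 0.999)
    wiou_normalize_distance: bool = True  # stability mode for training
    score_threshold: float = 0.05
    nms_threshold: float = 0.6

    # synthetic-data generation settings
    n_images: int = 16
    spike_count: tuple = (20, 40)
    spike_length: tuple | None = None   # None: derived from image_size
    spike_width: tuple | None = None
    split_ratio: float = 0.8

    def detector_config(self):
        from .detector import DetectorConfig

        return DetectorConfig(
            num_classes=self.num_classes,
            fpn_channels=self.fpn_channels,
            tower_convs=self.tower_convs,
            score_threshold=self.score_threshold,
            nms_threshold=self.nms_threshold,
        )

    def loss_configuration(self):
        from .detector import LossConfig

        return LossConfig(
            reg_loss=self.reg_loss,
            wiou_normalize_distance=self.wiou_normalize_distance,
        )

    def to_dict(self) -> dict:
        return asdict(self)


TINY_TEST_OVERRIDES = {
    "variant": "tiny",
    "fpn_channels": 32,
    "tower_convs": 1,
    "batch_size": 2,
    "image_size": 128,
    "spike_count": (4, 8),
    "spike_length": (36.0, 44.0),
    "spike_width": (8.0, 10.0),
    "warmup_iterations": 10,
    "learning_rate": 3e-3,
}


def load_run_config(path=None, overrides: dict | None = None,
                    tiny_test: bool = False) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides."""
    data: dict = {}
    if tiny_test:
        data.update(TINY_TEST_OVERRIDES)
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if data.get("adam_betas") is not None:
        data["adam_betas"] = tuple(data["adam_betas"])
    for key in ("spike_count", "spike_length", "spike_width"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    return RunConfig(**data)
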