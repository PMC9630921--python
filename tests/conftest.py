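import numpy as np
import pytest

from wheatformer.backbone import StageSpec, VariantSpec
from wheatformer.detector import DetectorConfig, WheatFormerDetector


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_detector():
    """Small shared detector for inference-path tests (weights untrained)."""
    return WheatFormerDetector(
        "tiny",
        rng=np.random.default_rng(123),
        config=DetectorConfig(fpn_channels=16, tower_convs=1),
    )


def make_stage_spec(channels=32, depth=2, window_sizes=(3, 5), head_dim=8,
                    mlp_ratio=2.0, sr_mode="identity"):
    return StageSpec(channels=channels, depth=depth, window_sizes=window_sizes,
                     head_dim=head_dim, mlp_ratio=mlp_ratio, sr_mode=sr_mode)


def random_boxes(rng, n, lo=0.0, hi=100.0, min_size=1.0, max_size=40.0):
    """(n, 4) random valid corner boxes."""
    x0 = rng.uniform(lo, hi - max_size, n)
    y0 = rng.uniform(lo, hi - max_size, n)
    w = rng.uniform(min_size, max_size, n)
    h = rng.uniform(min_size, max_size, n)
    return np.stack([x0, y0, x0 + w, y0 + h], axis=1)
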