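"""Hierarchical multi-window shifted-window attention backbone.

The backbone splits an image into 4x4 patches (48-dim tokens), linearly embeds
them to C channels and runs four stages of transformer blocks.  Each block's
attention runs three parallel windowed branches with window sizes [7, 9, 11];
branch outputs (each C channels) are concatenated and projected back to C.
Blocks alternate between unshifted and cyclically shifted windows.  A patch
merging layer between stages halves the grid and doubles the channels, so the
stage outputs sit at strides [4, 8, 16, 32] with channels [C, 2C, 4C, 8C].

Design notes
------------
* The spatial-reduction (SR) slot inside the block defaults to identity so the
  per-stage output resolutions stay exactly at strides [4, 8, 16, 32]; a
  literal per-block downsampling would shrink the map on every block and break
  that contract.  A reduce-restore bottleneck is available via
  ``StageSpec.sr_mode = "bottleneck:<r>"``.
* Patch merging sits *between* stages (three merges, none after stage 4).
* Heads per branch = channels / head_dim with head_dim 32 for the published
  variants; each branch owns its Q/K/V projection and relative-position-bias
  table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "StageSpec",
    "VariantSpec",
    "get_variant",
    "patch_partition",
    "pad_image",
    "window_partition",
    "window_reverse",
    "attention",
    "relative_position_index",
    "shifted_window_masks",
    "WindowBranch",
    "MultiWindowAttention",
    "SpatialReduction",
    "TransformerBlock",
    "PatchEmbed",
    "PatchMerging",
    "MWSwinBackbone",
    "count_backbone_parameters",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageSpec:
    channels: int
    depth: int
    window_sizes: tuple = (7, 9, 11)
    head_dim: int = 32
    mlp_ratio: float = 4.0
    sr_mode: str = "identity"

    def __post_init__(self):
        if self.channels % self.head_dim != 0:
            raise ValueError(
                f"channels {self.channels} not divisible by head_dim {self.head_dim}"
            )

    @property
    def num_heads(self) -> int:
        return self.channels // self.head_dim


@dataclass(frozen=True)
class VariantSpec:
    name: str
    stages: tuple  # four StageSpec
    patch_size: int = 4
    embed_dim: int = 96

    def __post_init__(self):
        if len(self.stages) != 4:
            raise ValueError("a variant has exactly four stages")
        if self.stages[0].channels != self.embed_dim:
            raise ValueError("stage-1 channels must equal embed_dim")

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "patch_size": self.patch_size,
                "embed_dim": self.embed_dim,
                "stages": [
                    {
                        "channels": s.channels,
                        "depth": s.depth,
                        "window_sizes": list(s.window_sizes),
                        "head_dim": s.head_dim,
                        "mlp_ratio": s.mlp_ratio,
                        "sr_mode": s.sr_mode,
                    }
                    for s in self.stages
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "VariantSpec":
        d = json.loads(text)
        stages = tuple(
            StageSpec(
                channels=s["channels"],
                depth=s["depth"],
                window_sizes=tuple(s["window_sizes"]),
                head_dim=s["head_dim"],
                mlp_ratio=s["mlp_ratio"],
                sr_mode=s["sr_mode"],
            )
            for s in d["stages"]
        )
        return cls(name=d["name"], stages=stages,
                   patch_size=d["patch_size"], embed_dim=d["embed_dim"])


def _make_variant(name: str, channels, depths, window_sizes=(7, 9, 11),
                  head_dim=32, mlp_ratio=4.0) -> VariantSpec:
    stages = tuple(
        StageSpec(channels=c, depth=d, window_sizes=tuple(window_sizes),
                  head_dim=head_dim, mlp_ratio=mlp_ratio)
        for c, d in zip(channels, depths)
    )
    return VariantSpec(name=name, stages=stages, embed_dim=channels[0])


def _load_variants() -> dict:
    """Variant definitions ship as a YAML config file inside the package."""
    import importlib.resources

    import yaml

    text = (
        importlib.resources.files("wheatformer") / "configs" / "variants.yaml"
    ).read_text()
    variants = {}
    for name, d in yaml.safe_load(text).items():
        variants[name] = _make_variant(
            name, d["channels"], d["depths"],
            window_sizes=tuple(d["window_sizes"]),
            head_dim=d["head_dim"], mlp_ratio=d["mlp_ratio"],
        )
    return variants


_VARIANTS: dict | None = None


def get_variant(name: str) -> VariantSpec:
    global _VARIANTS
    if _VARIANTS is None:
        _VARIANTS = _load_variants()
    try:
        return _VARIANTS[name]
    except KeyError:
        raise KeyError(f"unknown variant {name!r}; choose from {sorted(_VARIANTS)}")


# ---------------------------------------------------------------------------
# Token-level primitives
# ---------------------------------------------------------------------------

def pad_image(image: np.ndarray, multiple: int = 32) -> np.ndarray:
    """Zero-pad an (H, W, 3) or (B, H, W, 3) image bottom/right to a multiple."""
    image = np.asarray(image)
    h, w = image.shape[-3], image.shape[-2]
    ph = (multiple - h % multiple) % multiple
    pw = (multiple - w % multiple) % multiple
    if ph == 0 and pw == 0:
        return image
    pad = [(0, 0)] * image.ndim
    pad[-3] = (0, ph)
    pad[-2] = (0, pw)
    return np.pad(image, pad)


def patch_partition(image: np.ndarray, patch_size: int = 4) -> np.ndarray:
    """Split an RGB image into non-overlapping patches flattened to tokens.

    (H, W, 3) -> (H/p, W/p, 3 p^2); with the default p=4 each token is 48-dim.
    A leading batch dimension is preserved if present.
    """
    image = np.asarray(image, dtype=np.float64)
    squeeze = image.ndim == 3
    if squeeze:
        image = image[None]
    b, h, w, c = image.shape
    p = patch_size
    if h % p or w % p:
        raise ValueError(f"image dims ({h}, {w}) not divisible by patch size {p}")
    tokens = (
        image.reshape(b, h // p, p, w // p, p, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(b, h // p, w // p, p * p * c)
    )
    return tokens[0] if squeeze else tokens


def window_partition(x: Tensor, window: int):
    """Tile a (B, H, W, C) map into (B * nH * nW, window^2, C) windows.

    The grid is zero-padded bottom/right to window multiples first.  Returns
    ``(windows, (Hp, Wp))`` where (Hp, Wp) is the padded grid size needed by
    :func:`window_reverse`.
    """
    b, h, w, c = x.shape
    hp = -(-h // window) * window
    wp = -(-w // window) * window
    if hp != h or wp != w:
        x = x.pad(((0, 0), (0, hp - h), (0, wp - w), (0, 0)))
    nh, nw = hp // window, wp // window
    win = (
        x.reshape(b, nh, window, nw, window, c)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(b * nh * nw, window * window, c)
    )
    return win, (hp, wp)


def window_reverse(windows: Tensor, window: int, padded_hw, out_hw) -> Tensor:
    """Inverse of :func:`window_partition`, cropping padding back off."""
    hp, wp = padded_hw
    h, w = out_hw
    nh, nw = hp // window, wp // window
    b = windows.shape[0] // (nh * nw)
    x = (
        windows.reshape(b, nh, nw, window, window, windows.shape[-1])
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(b, hp, wp, windows.shape[-1])
    )
    return x[:, :h, :w, :]


def attention(q: Tensor, k: Tensor, v: Tensor, bias=None, mask=None) -> Tensor:
    """softmax(Q K^T / sqrt(d) + B [+ mask]) V over the last two axes.

    ``q``/``k``/``v`` are (..., n, d); ``bias`` and ``mask`` are additive
    arrays broadcastable to the (..., n, n) logits.
    """
    d = q.shape[-1]
    logits = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * (d ** -0.5)
    if bias is not None:
        logits = logits + bias
    if mask is not None:
        logits = logits + mask
    return nn.softmax(logits, axis=-1) @ v


def relative_position_index(window: int) -> np.ndarray:
    """Swin-style (n, n) index into a (2X-1)^2 relative-position-bias table."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                  indexing="ij")).reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]  # (2, n, n)
    rel = rel + (window - 1)
    return rel[0] * (2 * window - 1) + rel[1]


def shifted_window_masks(h: int, w: int, window: int, shift: int) -> np.ndarray:
    """Additive attention masks for a (possibly shifted) padded window grid.

    Returns (num_windows, n, n) with 0 where attention is allowed and -1e9
    where it is forbidden.  Tokens may attend within their window only if they
    originate from the same pre-shift region and the key is not a padding
    token; self-attention is always allowed (keeps padded rows finite).
    """
    hp = -(-h // window) * window
    wp = -(-w // window) * window
    region = np.zeros((hp, wp), dtype=np.int64)
    if shift > 0:
        cnt = 0
        for hs in (slice(0, hp - window), slice(hp - window, hp - shift),
                   slice(hp - shift, hp)):
            for ws in (slice(0, wp - window), slice(wp - window, wp - shift),
                       slice(wp - shift, wp)):
                region[hs, ws] = cnt
                cnt += 1
    padmap = np.zeros((hp, wp), dtype=bool)
    padmap[h:, :] = True
    padmap[:, w:] = True
    if shift > 0:
        region = np.roll(region, (-shift, -shift), axis=(0, 1))
        padmap = np.roll(padmap, (-shift, -shift), axis=(0, 1))
    nh, nw = hp // window, wp // window
    n = window * window
    reg_w = (
        region.reshape(nh, window, nw, window).transpose(0, 2, 1, 3).reshape(-1, n)
    )
    pad_w = (
        padmap.reshape(nh, window, nw, window).transpose(0, 2, 1, 3).reshape(-1, n)
    )
    allowed = (reg_w[:, :, None] == reg_w[:, None, :]) & ~pad_w[:, None, :]
    allowed |= np.eye(n, dtype=bool)[None]
    return np.where(allowed, 0.0, -1e9)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class WindowBranch(nn.Module):
    """One windowed-attention branch (own Q/K/V and bias table)."""

    def __init__(self, channels: int, window: int, num_heads: int,
                 rng: np.random.Generator, shift: int = 0):
        self.window = window
        self.shift = shift
        self.num_heads = num_heads
        self.head_dim = channels // num_heads
        self.channels = channels
        self.qkv = nn.Linear(channels, 3 * channels, rng)
        self.bias_table = nn.Parameter(
            nn.trunc_normal(rng, ((2 * window - 1) ** 2, num_heads))
        )
        self._rel_index = relative_position_index(window)
        self._mask_cache: dict = {}

    def _bias(self) -> Tensor:
        n = self.window * self.window
        b = self.bias_table[self._rel_index.reshape(-1)]  # (n*n, heads)
        return b.reshape(n, n, self.num_heads).transpose(2, 0, 1)  # (heads, n, n)

    def _masks(self, h: int, w: int) -> np.ndarray:
        key = (h, w)
        if key not in self._mask_cache:
            self._mask_cache[key] = shifted_window_masks(h, w, self.window, self.shift)
        return self._mask_cache[key]

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        X, s = self.window, self.shift
        hp = -(-h // X) * X
        wp = -(-w // X) * X
        if hp != h or wp != w:
            x = x.pad(((0, 0), (0, hp - h), (0, wp - w), (0, 0)))
        if s > 0:
            x = x.roll((-s, -s), axis=(1, 2))
        win, _ = window_partition(x, X)  # (b*nw, n, c), already multiple
        nwin = win.shape[0] // b
        n = X * X
        qkv = (
            self.qkv(win)
            .reshape(b * nwin, n, 3, self.num_heads, self.head_dim)
            .transpose(2, 0, 3, 1, 4)
        )
        q, k, v = qkv[0], qkv[1], qkv[2]  # each (b*nw, heads, n, d)
        d = self.head_dim
        logits = (q @ k.transpose(0, 1, 3, 2)) * (d ** -0.5) + self._bias()
        masks = self._masks(h, w)  # (nwin, n, n)
        logits = logits.reshape(b, nwin, self.num_heads, n, n) + masks[None, :, None]
        weights = nn.softmax(logits, axis=-1).reshape(b * nwin, self.num_heads, n, n)
        out = (weights @ v).transpose(0, 2, 1, 3).reshape(b * nwin, n, c)
        x = window_reverse(out, X, (hp, wp), (hp, wp))
        if s > 0:
            x = x.roll((s, s), axis=(1, 2))
        return x[:, :h, :w, :]


class MultiWindowAttention(nn.Module):
    """Parallel windowed branches, concatenated and projected back to C.

    With ``shift=True`` each branch cyclically shifts by floor(X_i / 2) before
    windowing (the shifted twin of the block pair).
    """

    def __init__(self, spec: StageSpec, rng: np.random.Generator, shift: bool = False):
        self.branches = [
            WindowBranch(
                spec.channels, X, spec.num_heads, rng,
                shift=(X // 2 if shift else 0),
            )
            for X in spec.window_sizes
        ]
        self.proj = nn.Linear(len(spec.window_sizes) * spec.channels, spec.channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        outs = [branch(x) for branch in self.branches]
        return self.proj(nn.concatenate(outs, axis=-1))


class SpatialReduction(nn.Module):
    """Optional reduce-restore bottleneck; the output grid always equals the
    input grid so the stage-resolution contract is preserved."""

    def __init__(self, channels: int, mode: str, rng: np.random.Generator):
        if mode == "identity":
            self.r = 1
            self.mix = None
        elif mode.startswith("bottleneck:"):
            self.r = int(mode.split(":", 1)[1])
            if self.r < 1:
                raise ValueError(f"bottleneck factor must be >= 1, got {self.r}")
            self.mix = nn.Linear(self.r * self.r * channels, channels, rng)
        else:
            raise ValueError(f"unknown sr_mode {mode!r}")

    def forward(self, x: Tensor) -> Tensor:
        if self.mix is None:
            return x
        r = self.r
        b, h, w, c = x.shape
        hp = -(-h // r) * r
        wp = -(-w // r) * r
        if hp != h or wp != w:
            x = x.pad(((0, 0), (0, hp - h), (0, wp - w), (0, 0)))
        grouped = (
            x.reshape(b, hp // r, r, wp // r, r, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, hp // r, wp // r, r * r * c)
        )
        mixed = self.mix(grouped)  # (b, hp/r, wp/r, c)
        ih = np.repeat(np.arange(hp // r), r)[:h]
        iw = np.repeat(np.arange(wp // r), r)[:w]
        return mixed[:, ih][:, :, iw]


class Mlp(nn.Module):
    def __init__(self, channels: int, ratio: float, rng: np.random.Generator):
        hidden = int(channels * ratio)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(nn.gelu(self.fc1(x)))


class TransformerBlock(nn.Module):
    """One block: z' = Attn(LN(z)) + z; z' = SR(z'); z = MLP(LN(z')) + z'."""

    def __init__(self, spec: StageSpec, rng: np.random.Generator, shift: bool):
        self.norm1 = nn.LayerNorm(spec.channels)
        self.attn = MultiWindowAttention(spec, rng, shift=shift)
        self.sr = SpatialReduction(spec.channels, spec.sr_mode, rng)
        self.norm2 = nn.LayerNorm(spec.channels)
        self.mlp = Mlp(spec.channels, spec.mlp_ratio, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.attn(self.norm1(x)) + x
        x = self.sr(x)
        return self.mlp(self.norm2(x)) + x


class PatchEmbed(nn.Module):
    def __init__(self, patch_size: int, embed_dim: int, rng: np.random.Generator):
        self.patch_size = patch_size
        self.proj = nn.Linear(3 * patch_size * patch_size, embed_dim, rng)

    def forward(self, image: np.ndarray) -> Tensor:
        tokens = patch_partition(image, self.patch_size)
        return self.proj(nn.as_tensor(tokens))


class PatchMerging(nn.Module):
    """2x2 token-group concat (4C) -> LayerNorm -> linear to 2C; grid halves."""

    def __init__(self, channels: int, rng: np.random.Generator):
        self.norm = nn.LayerNorm(4 * channels)
        self.reduction = nn.Linear(4 * channels, 2 * channels, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            x = x.pad(((0, 0), (0, h % 2), (0, w % 2), (0, 0)))
        x00 = x[:, 0::2, 0::2, :]
        x10 = x[:, 1::2, 0::2, :]
        x01 = x[:, 0::2, 1::2, :]
        x11 = x[:, 1::2, 1::2, :]
        merged = nn.concatenate([x00, x10, x01, x11], axis=-1)
        return self.reduction(self.norm(merged))


class MWSwinBackbone(nn.Module):
    """Four-stage hierarchical backbone; returns feature maps F1..F4 at
    strides [4, 8, 16, 32] with the variant's per-stage channels."""

    def __init__(self, variant: VariantSpec, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.variant = variant
        self.patch_embed = PatchEmbed(variant.patch_size, variant.embed_dim, rng)
        self.stages = []
        self.merges = []
        self.out_norms = []
        for i, spec in enumerate(variant.stages):
            blocks = [
                TransformerBlock(spec, rng, shift=(j % 2 == 1))
                for j in range(spec.depth)
            ]
            self.stages.append(blocks)
            if i < 3:
                self.merges.append(PatchMerging(spec.channels, rng))
            self.out_norms.append(nn.LayerNorm(spec.channels))

    def named_parameters(self, prefix: str = ""):
        yield from self.patch_embed.named_parameters(f"{prefix}patch_embed.")
        for i, blocks in enumerate(self.stages):
            for j, blk in enumerate(blocks):
                yield from blk.named_parameters(f"{prefix}stages.{i}.{j}.")
        for i, m in enumerate(self.merges):
            yield from m.named_parameters(f"{prefix}merges.{i}.")
        for i, m in enumerate(self.out_norms):
            yield from m.named_parameters(f"{prefix}out_norms.{i}.")

    def forward(self, image: np.ndarray) -> list[Tensor]:
        image = np.asarray(image, dtype=np.float64)
        h, w = image.shape[-3], image.shape[-2]
        if h < 32 or w < 32:
            raise ValueError(f"input image ({h}x{w}) smaller than 32x32")
        if h % 32 or w % 32:
            raise ValueError(
                f"input image ({h}x{w}) must be padded to a multiple of 32; "
                "use pad_image()"
            )
        x = self.patch_embed(image)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        feats = []
        for i, blocks in enumerate(self.stages):
            for blk in blocks:
                x = blk(x)
            feats.append(self.out_norms[i](x))
            if i < 3:
                x = self.merges[i](x)
        return feats


# ---------------------------------------------------------------------------
# Closed-form parameter counting
# ---------------------------------------------------------------------------

def _block_param_count(spec: StageSpec) -> int:
    c = spec.channels
    heads = spec.num_heads
    hidden = int(c * spec.mlp_ratio)
    total = 0
    total += 2 * (2 * c)  # two layer norms
    for X in spec.window_sizes:
        total += c * 3 * c + 3 * c           # qkv weight + bias
        total += (2 * X - 1) ** 2 * heads    # relative position bias table
    total += len(spec.window_sizes) * c * c + c  # concat projection
    total += c * hidden + hidden + hidden * c + c  # mlp
    if spec.sr_mode.startswith("bottleneck:"):
        r = int(spec.sr_mode.split(":", 1)[1])
        total += r * r * c * c + c
    return total


def count_backbone_parameters(variant: VariantSpec) -> int:
    """Closed-form learnable-parameter count; matches the instantiated
    :class:`MWSwinBackbone` exactly (asserted in the tests)."""
    c1 = variant.embed_dim
    total = 3 * variant.patch_size ** 2 * c1 + c1  # patch embedding
    for i, spec in enumerate(variant.stages):
        total += spec.depth * _block_param_count(spec)
        if i < 3:
            total += 2 * (4 * spec.channels)                   # merge norm
            total += 4 * spec.channels * 2 * spec.channels     # merge reduction
        total += 2 * spec.channels                             # output norm
    return total
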