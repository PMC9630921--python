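"""Neural-network building blocks on top of the autograd engine."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter, Tensor, exp, sigmoid, tanh

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "Conv2d",
    "softmax",
    "gelu",
    "trunc_normal",
]


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) with tails beyond 2 std re-drawn (cheap clip variant)."""
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std)


class Module:
    """Base class with recursive parameter discovery and flat state dicts."""

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{full}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map with fan-scaled (Glorot) truncated-normal weight init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        std = float(np.sqrt(2.0 / (in_features + out_features)))
        self.weight = Parameter(trunc_normal(rng, (in_features, out_features), std=std))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Conv2d(Module):
    """k x k convolution on channels-last maps (B, H, W, C), same padding.

    Implemented as a sum of shifted pointwise matmuls, which keeps the whole
    op inside the autograd primitive set.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, bias: bool = True):
        if kernel % 2 != 1:
            raise ValueError("only odd kernels supported")
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, in_ch, out_ch))
        )
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.kernel = kernel
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        k, s = self.kernel, self.stride
        b, h, w, _ = x.shape
        p = k // 2
        xp = x.pad(((0, 0), (p, p), (p, p), (0, 0)))
        oh = (h + s - 1) // s
        ow = (w + s - 1) // s
        out = None
        for dy in range(k):
            for dx in range(k):
                patch = xp[:, dy : dy + h : s, dx : dx + w : s, :]
                term = patch @ self.weight[dy, dx]
                out = term if out is None else out + term
        if self.bias is not None:
            out = out + self.bias
        assert out.shape[1] == oh and out.shape[2] == ow
        return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = np.max(x.data, axis=axis, keepdims=True)  # constant: ok under grad
    e = exp(x - shift)
    return e / e.sum(axis=axis, keepdims=True)


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    return 0.5 * x * (1.0 + tanh(_GELU_C * (x + 0.044715 * x * x * x)))


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling of a (B, H, W, C) map."""
    _, h, w, _ = x.shape
    ih = np.repeat(np.arange(h), 2)
    iw = np.repeat(np.arange(w), 2)
    return x[:, ih][:, :, iw]


def binary_cross_entropy_with_logits(logits: Tensor, targets) -> Tensor:
    """Elementwise stable BCE: softplus(x) - x * t."""
    from .tensor import softplus

    t = np.asarray(targets, dtype=np.float64)
    return softplus(logits) - logits * t


def sigmoid_focal_loss(logits: Tensor, targets, alpha: float = 0.25,
                       gamma: float = 2.0) -> Tensor:
    """Elementwise focal loss on binary logits (targets in {0,1})."""
    from .tensor import softplus

    t = np.asarray(targets, dtype=np.float64)
    p = sigmoid(logits)
    # log p = -softplus(-x); log(1-p) = -softplus(x)
    pos = (p * (-1.0) + 1.0) ** gamma * softplus(logits * (-1.0)) * alpha
    neg = p ** gamma * softplus(logits) * (1.0 - alpha)
    return pos * t + neg * (1.0 - t)
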