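"""Backbone: patch/window plumbing, multi-window attention oracles, variants."""

import numpy as np
import pytest

from wheatformer import nn
from wheatformer.backbone import (
    MWSwinBackbone,
    MultiWindowAttention,
    PatchEmbed,
    PatchMerging,
    SpatialReduction,
    StageSpec,
    TransformerBlock,
    VariantSpec,
    WindowBranch,
    attention,
    count_backbone_parameters,
    get_variant,
    patch_partition,
    pad_image,
    relative_position_index,
    window_partition,
    window_reverse,
)
from wheatformer.nn import Tensor

from conftest import make_stage_spec


# ---------------------------------------------------------------------------
# patch partition / embedding
# ---------------------------------------------------------------------------

def test_patch_token_dimension_is_48(rng):
    tokens = patch_partition(rng.random((64, 64, 3)))
    assert tokens.shape[-1] == 48


def test_patch_grid_224(rng):
    tokens = patch_partition(rng.random((224, 224, 3)))
    assert tokens.shape == (56, 56, 48)


def test_patch_partition_constant_image():
    tokens = patch_partition(np.full((32, 32, 3), 0.5))
    assert np.allclose(tokens, tokens[0, 0])


def test_patch_partition_preserves_values(rng):
    img = rng.random((8, 8, 3))
    tokens = patch_partition(img)
    # first token = first 4x4 patch, flattened row-major (y, x, channel)
    assert np.array_equal(tokens[0, 0], img[:4, :4, :].reshape(-1))


def test_patch_partition_rejects_indivisible(rng):
    with pytest.raises(ValueError):
        patch_partition(rng.random((30, 32, 3)))


def test_pad_image_to_multiple(rng):
    img = rng.random((50, 70, 3))
    padded = pad_image(img, 32)
    assert padded.shape == (64, 96, 3)
    assert np.array_equal(padded[:50, :70], img)
    assert np.all(padded[50:] == 0)


def test_linear_embed_shapes_and_zero(rng):
    embed = PatchEmbed(4, 96, rng)
    out = embed(np.zeros((224, 224, 3)))
    assert out.shape == (56, 56, 96)
    assert np.allclose(out.data, 0.0)  # zero input, zero bias


def test_linear_embed_identity_prefix(rng):
    embed = PatchEmbed(4, 96, rng)
    embed.proj.weight.data[:] = 0.0
    embed.proj.weight.data[:48, :48] = np.eye(48)
    img = rng.random((8, 8, 3))
    out = embed(img)
    assert np.allclose(out.data[..., :48], patch_partition(img))
    assert np.allclose(out.data[..., 48:], 0.0)


# ---------------------------------------------------------------------------
# window partition / reverse
# ---------------------------------------------------------------------------

def test_window_partition_counts(rng):
    x = Tensor(rng.random((1, 28, 28, 4)))
    win, _ = window_partition(x, 7)
    assert win.shape == (16, 49, 4)


def test_window_partition_pads_to_ceil(rng):
    x = Tensor(rng.random((1, 14, 14, 4)))
    win, (hp, wp) = window_partition(x, 9)
    assert (hp, wp) == (18, 18)
    assert win.shape == (4, 81, 4)


def test_window_roundtrip_exact(rng):
    x = Tensor(rng.random((2, 13, 17, 5)))
    win, padded = window_partition(x, 7)
    back = window_reverse(win, 7, padded, (13, 17))
    assert np.array_equal(back.data, x.data)


# ---------------------------------------------------------------------------
# attention primitive
# ---------------------------------------------------------------------------

def test_attention_single_token(rng):
    q = Tensor(rng.normal(size=(1, 1, 1, 4)))
    v = Tensor(rng.normal(size=(1, 1, 1, 4)))
    out = attention(q, q, v)
    assert np.allclose(out.data, v.data)


def test_attention_uniform_when_logits_flat(rng):
    n, d = 6, 4
    q = Tensor(np.zeros((1, n, d)))
    k = Tensor(rng.normal(size=(1, n, d)))
    v = Tensor(rng.normal(size=(1, n, d)))
    out = attention(q, k, v)
    assert np.allclose(out.data, v.data.mean(axis=1, keepdims=True))


def test_attention_brute_force_five_tokens(rng):
    n, d = 5, 8
    q, k, v = (rng.normal(size=(1, n, d)) for _ in range(3))
    bias = rng.normal(size=(n, n))
    out = attention(Tensor(q), Tensor(k), Tensor(v), bias=bias)
    logits = q[0] @ k[0].T / np.sqrt(d) + bias
    w = np.exp(logits - logits.max(axis=-1, keepdims=True))
    w /= w.sum(axis=-1, keepdims=True)
    assert np.allclose(out.data[0], w @ v[0], atol=1e-5)


# ---------------------------------------------------------------------------
# multi-window attention vs oracles
# ---------------------------------------------------------------------------

def dense_attention_oracle(x, branch: WindowBranch):
    """Dense full-map softmax attention with the branch's own projections."""
    b, h, w, c = x.shape
    tokens = x.reshape(b, h * w, c)
    qkv = tokens @ branch.qkv.weight.data + branch.qkv.bias.data
    heads, d = branch.num_heads, branch.head_dim
    qkv = qkv.reshape(b, h * w, 3, heads, d).transpose(2, 0, 3, 1, 4)
    q, k, v = qkv
    logits = q @ k.swapaxes(-1, -2) / np.sqrt(d)
    wgt = np.exp(logits - logits.max(-1, keepdims=True))
    wgt /= wgt.sum(-1, keepdims=True)
    out = (wgt @ v).transpose(0, 2, 1, 3).reshape(b, h, w, c)
    return out


def test_full_window_branch_equals_dense_attention(rng):
    c, h = 32, 8
    branch = WindowBranch(c, window=8, num_heads=4, rng=rng, shift=0)
    branch.bias_table.data[:] = 0.0
    x = rng.normal(size=(2, h, h, c))
    out = branch(Tensor(x))
    assert np.allclose(out.data, dense_attention_oracle(x, branch), atol=1e-5)


def shifted_neighborhood_oracle(x, branch: WindowBranch):
    """Per-token brute force: each token attends over its true shifted-window
    neighborhood (same post-shift window, same pre-shift region, non-pad),
    with relative-position bias; derived from coordinates from first
    principles, independent of the module's mask construction."""
    _, h, w, c = x.shape
    X, s = branch.window, branch.shift
    heads, d = branch.num_heads, branch.head_dim
    hp = -(-h // X) * X
    wp = -(-w // X) * X

    def region(y, xx):
        def f(v, vp):
            if s == 0:
                return 0
            if v < vp - X:
                return 0
            if v < vp - s:
                return 1
            return 2

        return 3 * f(y, hp) + f(xx, wp)

    def rolled(y, xx):
        return ((y - s) % hp, (xx - s) % wp)

    coords = [(y, xx) for y in range(hp) for xx in range(wp)]
    qkv_w, qkv_b = branch.qkv.weight.data, branch.qkv.bias.data
    out = np.zeros_like(x)
    for y, xx in [(y, xx) for y in range(h) for xx in range(w)]:
        yr, xr = rolled(y, xx)
        wy, wx = yr // X, xr // X
        neigh = []
        for y2, x2 in coords:
            yr2, xr2 = rolled(y2, x2)
            if (yr2 // X, xr2 // X) != (wy, wx):
                continue
            same_region = region(y2, x2) == region(y, xx)
            is_pad = y2 >= h or x2 >= w
            if (same_region and not is_pad) or (y2, x2) == (y, xx):
                neigh.append((y2, x2, yr2 % X, xr2 % X))
        token = x[0, y, xx]
        qkv = token @ qkv_w + qkv_b
        q = qkv[:c].reshape(heads, d)
        my_in = (yr % X, xr % X)
        for hd in range(heads):
            logits, vals = [], []
            for y2, x2, iy, ix in neigh:
                qkv2 = x[0, y2, x2] @ qkv_w + qkv_b
                k2 = qkv2[c : 2 * c].reshape(heads, d)[hd]
                v2 = qkv2[2 * c :].reshape(heads, d)[hd]
                rel = (my_in[0] - iy + X - 1) * (2 * X - 1) + (my_in[1] - ix + X - 1)
                logits.append(q[hd] @ k2 / np.sqrt(d) + branch.bias_table.data[rel, hd])
                vals.append(v2)
            logits = np.asarray(logits)
            wgt = np.exp(logits - logits.max())
            wgt /= wgt.sum()
            out[0, y, xx, hd * d : (hd + 1) * d] = wgt @ np.asarray(vals)
    return out


@pytest.mark.parametrize("h,w,window,shift", [(12, 12, 5, 2), (11, 11, 5, 2), (12, 12, 4, 0)])
def test_shifted_branch_matches_per_token_oracle(rng, h, w, window, shift):
    c = 8
    branch = WindowBranch(c, window=window, num_heads=2, rng=rng, shift=shift)
    x = rng.normal(size=(1, h, w, c))
    out = branch(Tensor(x))
    oracle = shifted_neighborhood_oracle(x, branch)
    assert np.allclose(out.data, oracle, atol=1e-8)


def test_shift_unshift_without_attention_is_identity(rng):
    x = Tensor(rng.random((1, 9, 9, 4)))
    shifted = x.roll((-2, -2), axis=(1, 2)).roll((2, 2), axis=(1, 2))
    assert np.array_equal(shifted.data, x.data)


def test_mask_blocks_cross_region_pairs():
    from wheatformer.backbone import shifted_window_masks

    masks = shifted_window_masks(12, 12, 5, 2)
    # some window must contain forbidden pairs (off-diagonal -1e9)
    assert (masks < 0).any()
    for m in masks:
        assert np.all(np.diag(m) == 0.0)


def test_mw_msa_preserves_shape_and_zero(rng):
    spec = make_stage_spec(channels=16, window_sizes=(3, 5), head_dim=8)
    attn = MultiWindowAttention(spec, rng)
    x = rng.normal(size=(1, 10, 12, 16))
    out = attn(Tensor(x))
    assert out.shape == (1, 10, 12, 16)
    # zero input with zero qkv/proj biases and zero bias tables -> zero output
    for branch in attn.branches:
        branch.bias_table.data[:] = 0.0
        branch.qkv.bias.data[:] = 0.0
    attn.proj.bias.data[:] = 0.0
    out0 = attn(Tensor(np.zeros((1, 6, 6, 16))))
    assert np.allclose(out0.data, 0.0)


def test_mw_msa_rejects_bad_head_config():
    with pytest.raises(ValueError):
        StageSpec(channels=30, depth=2, head_dim=8)


# ---------------------------------------------------------------------------
# spatial reduction
# ---------------------------------------------------------------------------

def test_sr_identity_bitwise(rng):
    sr = SpatialReduction(8, "identity", rng)
    x = Tensor(rng.random((1, 8, 8, 8)))
    assert sr(x) is x


def test_sr_bottleneck_preserves_grid_piecewise_constant(rng):
    sr = SpatialReduction(8, "bottleneck:2", rng)
    x = Tensor(rng.random((1, 8, 8, 8)))
    out = sr(x)
    assert out.shape == (1, 8, 8, 8)
    blocks = out.data.reshape(1, 4, 2, 4, 2, 8)
    assert np.allclose(blocks, blocks[:, :, :1, :, :1, :])


def test_sr_bottleneck_r1_is_pointwise_linear(rng):
    sr = SpatialReduction(8, "bottleneck:1", rng)
    x = rng.random((1, 5, 7, 8))
    out = sr(Tensor(x))
    expected = x @ sr.mix.weight.data + sr.mix.bias.data
    assert np.allclose(out.data, expected)


def test_sr_unknown_mode_raises(rng):
    with pytest.raises(ValueError):
        SpatialReduction(8, "pool", rng)


# ---------------------------------------------------------------------------
# transformer block
# ---------------------------------------------------------------------------

def test_block_preserves_shape(rng):
    spec = make_stage_spec(channels=16, window_sizes=(3,), head_dim=8)
    blk = TransformerBlock(spec, rng, shift=False)
    x = Tensor(rng.normal(size=(1, 7, 9, 16)))
    assert blk(x).shape == (1, 7, 9, 16)


def test_block_residual_identity_when_branches_zeroed(rng):
    spec = make_stage_spec(channels=16, window_sizes=(3, 5), head_dim=8)
    x = rng.normal(size=(1, 6, 6, 16))
    for shift in (False, True):
        blk = TransformerBlock(spec, rng, shift=shift)
        blk.attn.proj.weight.data[:] = 0.0
        blk.attn.proj.bias.data[:] = 0.0
        blk.mlp.fc2.weight.data[:] = 0.0
        blk.mlp.fc2.bias.data[:] = 0.0
        out = blk(Tensor(x))
        assert np.allclose(out.data, x)


def test_block_gradcheck_toy(rng):
    spec = make_stage_spec(channels=32, depth=2, window_sizes=(3,), head_dim=8)
    blk = TransformerBlock(spec, rng, shift=True)
    x0 = rng.normal(size=(1, 6, 6, 32))
    proj = rng.normal(size=(32, 1))

    def forward(arr):
        return float((blk(Tensor(arr)) @ Tensor(proj)).sum().data)

    x = Tensor(x0.copy(), requires_grad=True)
    (blk(x) @ Tensor(proj)).sum().backward()
    eps = 1e-5
    idx = [(0, 0, 0, 0), (0, 3, 2, 7), (0, 5, 5, 31), (0, 2, 4, 16)]
    for i in idx:
        pert = x0.copy()
        pert[i] += eps
        hi = forward(pert)
        pert[i] -= 2 * eps
        lo = forward(pert)
        num = (hi - lo) / (2 * eps)
        assert np.isclose(x.grad[i], num, rtol=1e-3, atol=1e-6)


# ---------------------------------------------------------------------------
# patch merging / full backbone
# ---------------------------------------------------------------------------

def test_patch_merge_halves_grid(rng):
    merge = PatchMerging(96, rng)
    out = merge(Tensor(rng.normal(size=(1, 56, 56, 96))))
    assert out.shape == (1, 28, 28, 192)


def test_patch_merge_constant_input_constant_output(rng):
    merge = PatchMerging(8, rng)
    out = merge(Tensor(np.full((1, 4, 4, 8), 3.0)))
    flat = out.data.reshape(-1, 16)
    assert np.allclose(flat, flat[0])


def test_patch_merge_odd_grid_pads(rng):
    merge = PatchMerging(8, rng)
    out = merge(Tensor(rng.normal(size=(1, 7, 7, 8))))
    assert out.shape == (1, 4, 4, 16)


def test_backbone_stage_shapes_224_variant_S(rng):
    model = MWSwinBackbone(get_variant("S"), rng=rng)
    feats = model(rng.random((224, 224, 3)))
    shapes = [f.shape for f in feats]
    assert shapes == [
        (1, 56, 56, 96),
        (1, 28, 28, 192),
        (1, 14, 14, 384),
        (1, 7, 7, 768),
    ]


def test_variant_shapes_agree_S_B():
    s, b = get_variant("S"), get_variant("B")
    assert [st.channels for st in s.stages] == [st.channels for st in b.stages]
    assert [st.depth for st in s.stages] != [st.depth for st in b.stages]


def test_backbone_resolution_contract_any_size(rng):
    model = MWSwinBackbone(get_variant("tiny"), rng=rng)
    for h, w in [(64, 96), (128, 128)]:
        feats = model(rng.random((h, w, 3)))
        for i, f in enumerate(feats):
            stride = 4 * 2**i
            assert f.shape[1:3] == (h // stride, w // stride)


def test_backbone_rejects_small_or_unpadded(rng):
    model = MWSwinBackbone(get_variant("tiny"), rng=rng)
    with pytest.raises(ValueError):
        model(rng.random((16, 16, 3)))
    with pytest.raises(ValueError):
        model(rng.random((100, 96, 3)))


def test_backbone_deterministic(rng):
    model = MWSwinBackbone(get_variant("tiny"), rng=np.random.default_rng(5))
    img = rng.random((64, 64, 3))
    a = model(img)
    b = model(img)
    for fa, fb in zip(a, b):
        assert np.array_equal(fa.data, fb.data)


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def test_count_matches_instantiation_tiny_and_S():
    for name in ("tiny", "S"):
        variant = get_variant(name)
        model = MWSwinBackbone(variant, rng=np.random.default_rng(0))
        assert model.num_parameters() == count_backbone_parameters(variant)


def test_count_difference_B_minus_S_is_four_stage3_blocks():
    from wheatformer.backbone import _block_param_count

    s, b = get_variant("S"), get_variant("B")
    per_block = _block_param_count(b.stages[2])
    assert count_backbone_parameters(b) - count_backbone_parameters(s) == 4 * per_block


def test_count_ordering():
    counts = [count_backbone_parameters(get_variant(n)) for n in ("S", "B", "L")]
    assert counts[0] < counts[1] < counts[2]


def test_relative_position_index_properties():
    idx = relative_position_index(5)
    assert idx.shape == (25, 25)
    assert idx.min() >= 0 and idx.max() < 81
    assert np.all(np.diag(idx) == idx[0, 0])  # zero offset everywhere on diag


def test_variant_spec_json_roundtrip():
    v = get_variant("B")
    assert VariantSpec.from_json(v.to_json()) == v
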