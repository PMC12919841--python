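"""Hand-computed examples and loop-oracle equivalence for PCAB and SCAB."""

import math

import numpy as np
import pytest

from cogattn import nn
from cogattn._tensor import Tensor, no_grad
from cogattn.attention import (AttentionConfig, PCAB, SCAB, channel_branch,
                               make_block, pcab_forward,
                               pool_channel_descriptors,
                               pool_spatial_descriptors, scab_forward,
                               shared_mlp, spatial_branch)
from conftest import identity_mlp_block
from _reference import (block_params, randomize_block, ref_pcab, ref_scab)


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

def test_config_defaults_and_effective_field():
    cfg = AttentionConfig()
    assert (cfg.reduction_ratio, cfg.kernel_size, cfg.dilation) == (16, 7, 2)
    assert cfg.effective_dilation == 2
    assert cfg.effective_field == 13          # 7 + 6 * (2 - 1)
    std = AttentionConfig(conv_mode="standard")
    assert std.effective_dilation == 1 and std.effective_field == 7


@pytest.mark.parametrize("kwargs", [
    {"kernel_size": 4}, {"kernel_size": 0}, {"reduction_ratio": 0},
    {"dilation": 0}, {"pooling_mode": "median"}, {"conv_mode": "huge"},
    {"channel_fusion": "concat"},
])
def test_config_rejects_invalid_values(kwargs):
    with pytest.raises(ValueError):
        AttentionConfig(**kwargs)


def test_feature_map_validation():
    block = identity_mlp_block("pcab")
    with pytest.raises(ValueError):
        pcab_forward(np.zeros((2, 4)), block)          # not 3-D
    with pytest.raises(ValueError):
        pcab_forward(np.full((2, 3, 3), np.nan), block)  # non-finite
    with pytest.raises(TypeError):
        scab_forward(np.zeros((2, 3, 3)), block)       # wrong block kind


# ---------------------------------------------------------------------------
# pooling descriptors: hand values
# ---------------------------------------------------------------------------

def test_channel_pooling_hand_example():
    # channel 0: [[1,2],[3,4]] -> avg 2.5, max 4; channel 1: [[0,0],[0,8]]
    f = np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.0, 0.0], [0.0, 8.0]]])
    avg, mx = pool_channel_descriptors(f)
    np.testing.assert_allclose(avg, [2.5, 2.0])
    np.testing.assert_allclose(mx, [4.0, 8.0])
    avg_only, none_max = pool_channel_descriptors(f, "avg_only")
    assert none_max is None and np.allclose(avg_only, [2.5, 2.0])


def test_spatial_pooling_hand_example():
    f = np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.0, 0.0], [0.0, 8.0]]])
    avg, mx = pool_spatial_descriptors(f)
    np.testing.assert_allclose(avg, [[0.5, 1.0], [1.5, 6.0]])
    np.testing.assert_allclose(mx, [[1.0, 2.0], [3.0, 8.0]])


# ---------------------------------------------------------------------------
# channel branch on an identity MLP
# ---------------------------------------------------------------------------

def test_identity_mlp_channel_logits_are_summed_descriptors():
    # with W1 = W2 = I and zero biases, MLP(v) = relu(v) composed linearly:
    # for nonnegative descriptors, MLP(avg) + MLP(max) = avg + max
    block = identity_mlp_block("pcab", channels=2)
    f = np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.0, 0.0], [0.0, 8.0]]])
    logits = channel_branch(f, block, apply_sigmoid=False)
    np.testing.assert_allclose(logits, [2.5 + 4.0, 2.0 + 8.0], atol=1e-6)
    gated = channel_branch(f, block, apply_sigmoid=True)
    np.testing.assert_allclose(gated, sigmoid([6.5, 10.0]), atol=1e-6)


def test_channel_fusion_modes_agree_on_identity_mlp():
    # an identity MLP is linear on nonnegative inputs, so summing before or
    # after the MLP gives the same result there; a bent MLP separates them
    f = np.abs(np.random.default_rng(3).normal(size=(2, 3, 3))) + 0.1
    a = identity_mlp_block("pcab", 2, AttentionConfig(
        reduction_ratio=1, channel_fusion="mlp_then_sum"))
    b = identity_mlp_block("pcab", 2, AttentionConfig(
        reduction_ratio=1, channel_fusion="sum_then_mlp"))
    np.testing.assert_allclose(channel_branch(f, a, False),
                               channel_branch(f, b, False), atol=1e-6)


def test_channel_fusion_modes_differ_for_nonlinear_mlp():
    rng = np.random.default_rng(5)
    cfg_a = AttentionConfig(reduction_ratio=2, channel_fusion="mlp_then_sum")
    cfg_b = AttentionConfig(reduction_ratio=2, channel_fusion="sum_then_mlp")
    nn.manual_seed(11)
    a = PCAB(8, cfg_a)
    nn.manual_seed(11)
    b = PCAB(8, cfg_b)
    f = rng.normal(size=(8, 4, 4))
    out_a = channel_branch(f, a, False)
    out_b = channel_branch(f, b, False)
    assert not np.allclose(out_a, out_b)


def test_shared_mlp_hand_example():
    block = identity_mlp_block("pcab", channels=3,
                               config=AttentionConfig(reduction_ratio=1))
    # identity MLP clips negatives at the hidden relu
    np.testing.assert_allclose(shared_mlp([1.0, -2.0, 0.5], block),
                               [1.0, 0.0, 0.5], atol=1e-6)


def test_mlp_bottleneck_width():
    assert PCAB(64).hidden == 4            # 64 // 16
    assert PCAB(8).hidden == 1             # floor clamps to >= 1
    assert PCAB(32, AttentionConfig(reduction_ratio=4)).hidden == 8


# ---------------------------------------------------------------------------
# spatial branch
# ---------------------------------------------------------------------------

def test_spatial_branch_zeroed_conv_gives_half_map():
    # conv and BN affine zeroed -> logits 0 everywhere -> sigmoid = 0.5
    block = identity_mlp_block("pcab", channels=2)
    f = np.random.default_rng(0).normal(size=(2, 5, 6))
    ms = spatial_branch(f, block, apply_sigmoid=True)
    assert ms.shape == (5, 6)
    np.testing.assert_allclose(ms, 0.5, atol=1e-7)


def test_spatial_conv_impulse_reveals_dilated_taps():
    # k=3, d=2: an impulse response must appear at offsets {-2, 0, +2}
    cfg = AttentionConfig(kernel_size=3, dilation=2, conv_bias=False)
    block = PCAB(1, cfg)
    w = np.zeros((1, 1, 3, 3), dtype=np.float32)
    w[0, 0, 0, 0] = 1.0   # top-left tap
    block.spatial_conv.weight.data = w
    block.spatial_bn.weight.data = np.ones(1, dtype=np.float32)
    block.spatial_bn.bias.data = np.zeros(1, dtype=np.float32)
    block.eval()
    f = np.zeros((1, 9, 9))
    f[0, 4, 4] = 2.0      # impulse; avg+max across 1 channel doubles it -> 4
    ms = spatial_branch(f, block, apply_sigmoid=False)
    # top-left tap reads input at (h-2, w-2), so the response lands at (6, 6)
    invstd = 1.0 / math.sqrt(1.0 + 1e-5)
    assert abs(ms[6, 6] - 4.0 * invstd) < 1e-5
    ms[6, 6] = 0.0
    np.testing.assert_allclose(ms, 0.0, atol=1e-6)


def test_standard_conv_mode_forces_dilation_one():
    block = PCAB(4, AttentionConfig(conv_mode="standard", dilation=2))
    assert block.spatial_conv.dilation == 1
    assert block.spatial_conv.padding == 3     # (7 - 1) // 2
    dil = PCAB(4, AttentionConfig(conv_mode="dilated", dilation=2))
    assert dil.spatial_conv.dilation == 2 and dil.spatial_conv.padding == 6


# ---------------------------------------------------------------------------
# full block forwards: hand example and loop oracle
# ---------------------------------------------------------------------------

def test_pcab_zeroed_spatial_hand_example():
    # spatial logits 0 => M_CS = sigmoid(M_C); identity MLP gives M_C exactly
    block = identity_mlp_block("pcab", channels=2)
    f = np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.0, 0.0], [0.0, 8.0]]])
    out = pcab_forward(f, block)
    gate = sigmoid([6.5, 10.0]).reshape(2, 1, 1)
    np.testing.assert_allclose(out, f + f * gate, atol=1e-5)


def test_scab_zeroed_spatial_hand_example():
    # channel gate sigmoid(M_C) applied first, then spatial gate 0.5
    block = identity_mlp_block("scab", channels=2)
    f = np.array([[[1.0, 2.0], [3.0, 4.0]], [[0.0, 0.0], [0.0, 8.0]]])
    out = scab_forward(f, block)
    fc = f * sigmoid([6.5, 10.0]).reshape(2, 1, 1)
    np.testing.assert_allclose(out, f + fc * 0.5, atol=1e-5)


@pytest.mark.parametrize("kind", ["pcab", "scab"])
@pytest.mark.parametrize("mode", ["avg_only", "max_only", "avg_plus_max"])
def test_block_forward_matches_loop_oracle(kind, mode):
    mode_id = {"avg_only": 0, "max_only": 1, "avg_plus_max": 2}[mode]
    rng = np.random.default_rng([mode_id, int(kind == "pcab")])
    cfg = AttentionConfig(reduction_ratio=2, kernel_size=3, dilation=2,
                          pooling_mode=mode)
    block = make_block(kind, 5, cfg)
    randomize_block(block, rng)
    block.eval()
    params = block_params(block)
    f = rng.normal(size=(5, 6, 7))
    got = (pcab_forward if kind == "pcab" else scab_forward)(f, block)
    ref = (ref_pcab if kind == "pcab" else ref_scab)(f, params, mode=mode)
    np.testing.assert_allclose(got, ref, atol=1e-5)


def test_block_forward_matches_oracle_sum_then_mlp():
    rng = np.random.default_rng(99)
    cfg = AttentionConfig(reduction_ratio=2, kernel_size=3,
                          channel_fusion="sum_then_mlp")
    block = make_block("pcab", 4, cfg)
    randomize_block(block, rng)
    block.eval()
    got = pcab_forward(f := rng.normal(size=(4, 5, 5)), block)
    ref = ref_pcab(f, block_params(block), fusion="sum_then_mlp")
    np.testing.assert_allclose(got, ref, atol=1e-5)


# ---------------------------------------------------------------------------
# structural properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("kind", ["pcab", "scab"])
def test_shape_preserved_and_gain_bounded(kind):
    rng = np.random.default_rng(17)
    for c, h, w in [(1, 1, 1), (3, 8, 8), (16, 5, 9)]:
        block = make_block(kind, c, AttentionConfig(reduction_ratio=4,
                                                    kernel_size=3))
        randomize_block(block, rng)
        f = rng.normal(size=(c, h, w))
        out = (pcab_forward if kind == "pcab" else scab_forward)(f, block)
        assert out.shape == f.shape
        # every gate lies in (0,1), so |out| <= 2 |f| elementwise
        assert np.all(np.abs(out) <= 2 * np.abs(f) + 1e-9)


def test_zero_input_is_fixed_point():
    for kind in ("pcab", "scab"):
        block = make_block(kind, 3, AttentionConfig(reduction_ratio=1,
                                                    kernel_size=3))
        out = (pcab_forward if kind == "pcab" else scab_forward)(
            np.zeros((3, 4, 4)), block)
        np.testing.assert_allclose(out, 0.0, atol=1e-7)


def test_scab_differs_from_pcab_on_shared_weights():
    # sequential composition recomputes the spatial map from gated features,
    # so with identical weights the two blocks disagree in general
    rng = np.random.default_rng(31)
    cfg = AttentionConfig(reduction_ratio=2, kernel_size=3)
    nn.manual_seed(5)
    p = PCAB(6, cfg)
    s = SCAB(6, cfg)
    s.load_state_dict(p.state_dict())
    randomize_block(p, np.random.default_rng(31))
    s.load_state_dict(p.state_dict())
    f = rng.normal(size=(6, 5, 5))
    assert not np.allclose(pcab_forward(f, p), scab_forward(f, s))


def test_batched_forward_is_per_sample_independent():
    rng = np.random.default_rng(8)
    block = make_block("scab", 4, AttentionConfig(reduction_ratio=2,
                                                  kernel_size=3))
    randomize_block(block, rng)
    block.eval()
    batch = rng.normal(size=(3, 4, 6, 6)).astype(np.float32)
    with no_grad():
        joint = block(Tensor(batch)).data
    for i in range(3):
        np.testing.assert_allclose(joint[i], scab_forward(batch[i], block),
                                   atol=1e-5)


def test_blocks_are_trainable_end_to_end():
    # gradients reach every attention parameter through the residual path
    block = make_block("pcab", 4, AttentionConfig(reduction_ratio=2,
                                                  kernel_size=3))
    block.train()
    x = Tensor(np.random.default_rng(2).normal(size=(2, 4, 5, 5)),
               requires_grad=True)
    block(x).sum().backward()
    for name, p in block.named_parameters():
        assert p.grad is not None, name
        assert np.all(np.isfinite(p.grad)), name
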