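"""Behavioural tests for the bespoke blocks.

Each block is compared elementwise against an independent nested-loop
implementation of its defining equations (normalisation disabled, fixed
small weights), and checked for its shape contract, gate ranges,
zero-weight identities and the absence of dead (gradient-free) branches.
"""

import numpy as np
import pytest

from conftest import randomize_weights, set_constant_weights
from lesionseg import autograd as ag
from lesionseg.autograd import Tensor
from lesionseg.blocks import (BlockConfig, CalibratedConv, DilatedAttention,
                              EcaGate, FusionSkip, SigmoidAttention,
                              eca_weights)
from oracles import (attention_ref, calibrated_ref, dilated_attention_ref,
                     fusion_ref)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


# ---------------------------------------------------------------------------
# configuration invariants
# ---------------------------------------------------------------------------

def test_block_config_validation():
    cfg = BlockConfig(channels=8)
    assert cfg.calib_dilation == 7 and cfg.attention_dilations == (2, 4, 6)
    with pytest.raises(ValueError):
        BlockConfig(channels=7)  # calibrated conv splits channels in half
    with pytest.raises(ValueError):
        BlockConfig(channels=8, attention_dilations=(2, 2, 6))
    with pytest.raises(ValueError):
        BlockConfig(channels=8, attention_dilations=(6, 4, 2))


# ---------------------------------------------------------------------------
# calibrated split convolution
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("shape", [(1, 8, 32, 32), (2, 4, 16, 8), (1, 2, 8, 8)])
def test_calibrated_conv_preserves_shape(rng, shape):
    block = CalibratedConv(shape[1], rng)
    out = block(Tensor(rng.normal(size=shape)))
    assert out.shape == shape


def test_calibrated_conv_rejects_bad_inputs(rng):
    with pytest.raises(ValueError):
        CalibratedConv(7, rng)  # odd width cannot be split
    block = CalibratedConv(8, rng)
    with pytest.raises(ValueError):
        block(Tensor(rng.normal(size=(1, 7, 8, 8))))
    with pytest.raises(ValueError):
        block(Tensor(rng.normal(size=(1, 8, 1, 8))))  # 2x2 pooling impossible


def test_calibrated_conv_matches_loop_oracle_uniform_kernels(rng):
    """All-ones input, kernels fixed to 1/fan-in, norm off: the block must
    equal a literal scalar-loop evaluation of its two branches."""
    block = CalibratedConv(2, rng, norm=False)
    set_constant_weights(block, lambda shape, fan_in: np.full(shape, 1.0 / fan_in))
    x = np.ones((1, 2, 8, 8))
    got = block(Tensor(x)).data
    np.testing.assert_allclose(got, calibrated_ref(block, x), atol=1e-5)


@pytest.mark.parametrize("channels,size", [(2, 8), (4, 6), (6, 8)])
def test_calibrated_conv_matches_loop_oracle_random_weights(rng, channels, size):
    block = CalibratedConv(channels, rng, norm=False)
    randomize_weights(block, rng)
    x = rng.normal(size=(1, channels, size, size))
    got = block(Tensor(x)).data
    np.testing.assert_allclose(got, calibrated_ref(block, x), atol=1e-5)


# ---------------------------------------------------------------------------
# symmetric fusion skip
# ---------------------------------------------------------------------------

def test_fusion_skip_shape_contract(rng):
    block = FusionSkip(8, rng)
    x_high = Tensor(rng.normal(size=(1, 16, 16, 16)))
    y_low = Tensor(rng.normal(size=(1, 8, 32, 32)))
    assert block(x_high, y_low).shape == (1, 8, 32, 32)


def test_fusion_skip_rejects_ratio_violations(rng):
    block = FusionSkip(8, rng)
    with pytest.raises(ValueError):
        block(Tensor(np.zeros((1, 12, 16, 16))), Tensor(np.zeros((1, 8, 32, 32))))
    with pytest.raises(ValueError):
        block(Tensor(np.zeros((1, 16, 20, 20))), Tensor(np.zeros((1, 8, 32, 32))))


def test_fusion_skip_zero_weights_is_identity_on_low_input(rng):
    """With all conv weights zero the gated product vanishes and the block
    reduces to its residual: output == y_low exactly."""
    block = FusionSkip(4, rng)
    set_constant_weights(block, lambda shape, fan_in: np.zeros(shape))
    y_low = rng.normal(size=(1, 4, 16, 16))
    out = block(Tensor(rng.normal(size=(1, 8, 8, 8))), Tensor(y_low)).data
    np.testing.assert_array_equal(out, y_low)


def test_fusion_skip_matches_loop_oracle(rng):
    block = FusionSkip(2, rng, norm=False)
    randomize_weights(block, rng)
    x_high = rng.normal(size=(1, 4, 4, 4))
    y_low = rng.normal(size=(1, 2, 8, 8))
    got = block(Tensor(x_high), Tensor(y_low)).data
    np.testing.assert_allclose(got, fusion_ref(block, x_high, y_low), atol=1e-5)


# ---------------------------------------------------------------------------
# sigmoid self-attention and the dilated-attention bottleneck
# ---------------------------------------------------------------------------

def test_attention_shape_and_affinity_range(rng):
    att = SigmoidAttention(4, rng)
    a = Tensor(rng.normal(size=(1, 4, 16, 16)))
    assert att(a).shape == (1, 4, 16, 16)
    s = att.affinity(a).data
    assert s.shape == (1, 256, 256)
    assert np.all(s > 0.0) and np.all(s < 1.0)


def test_attention_matches_hand_matrix_oracle(rng):
    att = SigmoidAttention(2, rng, reduction=2, norm=False)
    randomize_weights(att, rng, scale=0.5)
    a = rng.normal(size=(1, 2, 2, 2))
    got = att(Tensor(a)).data
    np.testing.assert_allclose(got, attention_ref(att, a), atol=1e-8)


def test_dilated_attention_shape_and_structure(rng):
    block = DilatedAttention(8, rng, dilations=(2, 4, 6))
    out = block(Tensor(rng.normal(size=(1, 8, 16, 16))))
    assert out.shape == (1, 8, 16, 16)
    # the graph really contains one dilated branch per configured rate
    assert tuple(conv.conv.dilation for conv in block.dilated) == (2, 4, 6)
    assert len(block.attend) == 3


def test_dilated_attention_alternative_rate_combinations(rng):
    block = DilatedAttention(4, rng, dilations=(2, 6, 12))
    assert tuple(c.conv.dilation for c in block.dilated) == (2, 6, 12)
    out = block(Tensor(rng.normal(size=(1, 4, 8, 8))))
    assert out.shape == (1, 4, 8, 8)


def test_pooling_branch_reproduces_constant_input(rng):
    """Identity 1x1 conv + norm off: the image-level pooling branch of a
    spatially constant map returns that constant map."""
    block = DilatedAttention(3, rng, norm=False)
    block.pool_proj.conv.weight.data = np.eye(3).reshape(3, 3, 1, 1)
    block.pool_proj.conv.bias.data = np.zeros(3)
    x = Tensor(np.broadcast_to(
        np.array([1.0, 2.0, 3.0]).reshape(1, 3, 1, 1), (1, 3, 8, 8)).copy())
    out = block.pooling_branch(x).data
    np.testing.assert_allclose(out, x.data, atol=1e-12)


def test_dilated_attention_matches_loop_oracle(rng):
    block = DilatedAttention(2, rng, dilations=(1, 2, 3), reduction=2, norm=False)
    randomize_weights(block, rng)
    x = rng.normal(size=(1, 2, 4, 4))
    got = block(Tensor(x)).data
    np.testing.assert_allclose(got, dilated_attention_ref(block, x), atol=1e-5)


# ---------------------------------------------------------------------------
# channel attention (ECA, non-residual)
# ---------------------------------------------------------------------------

def test_eca_constant_channels_give_equal_weights(rng):
    x = np.full((2, 5, 4, 4), 0.7)
    w = eca_weights(x, 3)
    assert w.shape == (2, 5)
    np.testing.assert_allclose(w.data, np.broadcast_to(w.data[:, :1], (2, 5)),
                               atol=1e-12)
    assert np.all(w.data > 0) and np.all(w.data < 1)


def test_eca_identity_kernel_evaluates_sigmoid_of_channel_means():
    means = np.array([1.0, 2.0, 3.0, 4.0])
    x = np.broadcast_to(means.reshape(1, 4, 1, 1), (1, 4, 2, 2)).copy()
    w = eca_weights(x, 3, weight=[0.0, 1.0, 0.0], bias=0.0)
    np.testing.assert_allclose(w.data[0], _sigmoid(means), atol=1e-12)


def test_eca_rejects_even_kernel():
    with pytest.raises(ValueError):
        EcaGate(4)


def test_eca_apply_is_single_non_residual_multiplication(rng):
    gate = EcaGate(3, rng)
    x = Tensor(rng.normal(size=(1, 6, 4, 4)))
    w = gate.weights(x).data
    np.testing.assert_allclose(gate.apply(x).data,
                               x.data * w[:, :, None, None], atol=1e-12)


# ---------------------------------------------------------------------------
# no dead branches: every parameter receives gradient
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("make", [
    lambda rng: (CalibratedConv(4, rng), ((2, 4, 8, 8),)),
    lambda rng: (FusionSkip(4, rng), ((2, 8, 4, 4), (2, 4, 8, 8))),
    lambda rng: (DilatedAttention(4, rng), ((2, 4, 8, 8),)),
], ids=["calibrated", "fusion", "dilated-attention"])
def test_every_block_parameter_receives_gradient(rng, make):
    # batch of 2: batch norm on the 1x1 image-pooling branch needs more than
    # one value per channel for its statistics to pass any signal through
    block, shapes = make(rng)
    inputs = [Tensor(rng.normal(size=s) + 0.5) for s in shapes]
    out = block(*inputs)
    (out * Tensor(rng.normal(size=out.shape))).sum().backward()
    for name, p in block.named_parameters():
        assert p.grad is not None and np.any(p.grad != 0.0), \
            f"parameter {name} received no gradient"
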