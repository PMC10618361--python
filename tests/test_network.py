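"""Architecture contracts: shapes, stride, parameter accounting, SE behaviour."""

import numpy as np
import pytest

import nerveseg.nn as nn
from nerveseg.network import (
    NetworkConfig,
    ShapeError,
    build_bottleneck_block,
    build_se_block,
    build_network,
    complexity_report,
)

DESK = NetworkConfig(levels=3, base_width=8)


# ---------------------------------------------------------------------------
# bottleneck block
# ---------------------------------------------------------------------------


def test_bottleneck_block_preserves_spatial_shape(rng):
    blk = build_bottleneck_block(16, 24, 4, rng=rng)
    x = rng.normal(0, 1, (1, 16, 8, 8, 8)).astype("f4")
    out = blk(nn.Tensor(x))
    assert out.shape == (1, 24, 8, 8, 8)


def test_bottleneck_parameter_count_closed_form():
    """reduce 16->4 (68) + 3x3x3 conv 4->4 (436) + expand 4->16 (80) = 584."""
    blk = build_bottleneck_block(16, 16, 4)
    assert sum(p.data.size for p in blk.parameters()) == 584


def test_zeroed_expansion_makes_block_an_identity(rng):
    blk = build_bottleneck_block(16, 16, 4, rng=rng)
    blk.expand.weight.data[:] = 0.0
    blk.expand.bias.data[:] = 0.0
    x = np.abs(rng.normal(0, 1, (1, 16, 6, 6, 6))).astype("f4")  # positive: relu transparent
    out = blk(nn.Tensor(x))
    np.testing.assert_allclose(out.data, x, atol=1e-6)


def test_tiny_width_clamps_mid_channels_with_warning():
    with pytest.warns(UserWarning):
        blk = build_bottleneck_block(2, 2, 4)
    out = blk(nn.Tensor(np.zeros((1, 2, 4, 4, 4), "f4")))
    assert out.shape == (1, 2, 4, 4, 4)


# ---------------------------------------------------------------------------
# squeeze-and-excitation
# ---------------------------------------------------------------------------


def test_se_zero_input_zero_output(rng):
    se = build_se_block(8, 2, rng)
    out = se(nn.Tensor(np.zeros((1, 8, 4, 4, 4), "f4")))
    assert not out.data.any()


def test_se_gate_attenuates_magnitudes(rng):
    se = build_se_block(8, 2, rng)
    for seed in range(20):
        x = np.random.default_rng(seed).normal(0, 1, (1, 8, 4, 4, 4)).astype("f4")
        out = se(nn.Tensor(x))
        assert np.all(np.abs(out.data) <= np.abs(x) + 1e-7)


def test_se_preserves_spatial_constancy(rng):
    se = build_se_block(4, 2, rng)
    x = np.broadcast_to(
        rng.normal(0, 1, (1, 4, 1, 1, 1)).astype("f4"), (1, 4, 5, 5, 5)
    ).copy()
    out = se(nn.Tensor(x)).data
    for c in range(4):
        assert np.ptp(out[0, c]) < 1e-7


# ---------------------------------------------------------------------------
# full network
# ---------------------------------------------------------------------------


def test_forward_shape_and_channel_softmax(rng):
    net = build_network(DESK, seed=0)
    x = rng.normal(0, 1, (1, 1, 8, 16, 16)).astype("f4")
    out = net(x)
    assert out.shape == (1, 2, 8, 16, 16)
    np.testing.assert_allclose(out.data.sum(axis=1), 1.0, atol=1e-5)


def test_indivisible_input_raises_shape_error():
    net = build_network(NetworkConfig(levels=5, base_width=8), seed=0)
    with pytest.raises(ShapeError, match="axis 0"):
        net(np.zeros((1, 1, 30, 64, 64), "f4"))


def test_default_max_stride_is_16():
    assert NetworkConfig().max_stride == 16
    # the coarsest encoder feature map is input/16 on each axis
    net = build_network(NetworkConfig(base_width=4), seed=0)
    net(np.zeros((1, 1, 16, 16, 32), "f4"))
    coarsest = min(
        m.last_output_voxels for m in net.modules()
        if isinstance(m, nn.Conv3d) and m.last_output_voxels
    )
    assert coarsest == (16 // 16) * (16 // 16) * (32 // 16)


def test_bottleneck_se_variant_has_fewer_parameters_than_plain():
    small = NetworkConfig(levels=3, base_width=8)
    light = complexity_report(build_network(small), (16, 16, 16))
    plain_cfg = NetworkConfig(levels=3, base_width=8, use_bottleneck=False, use_se=False)
    plain = complexity_report(build_network(plain_cfg), (16, 16, 16))
    assert light.parameters < plain.parameters


def test_parameter_count_matches_enumeration_and_single_conv_closed_form(rng):
    conv = nn.Conv3d(1, 8, 3, padding=1, rng=rng)
    assert sum(p.data.size for _, p in
               [("w", conv.weight), ("b", conv.bias)]) == 27 * 8 + 8
    conv(nn.Tensor(np.zeros((1, 1, 16, 16, 16), "f4")))
    assert conv.last_output_voxels == 16**3
    # MAC closed form for that conv: 27 * 1 * 8 * 16^3
    net = build_network(DESK, seed=0)
    rep = complexity_report(net, (16, 16, 16))
    assert rep.parameters == sum(p.data.size for p in net.parameters())
    assert rep.deployment_bytes == rep.parameters * 4


def test_doubling_width_quadruples_conv_weights():
    def conv_weights(base_width):
        net = build_network(NetworkConfig(levels=3, base_width=base_width), seed=0)
        return sum(
            m.weight.data.size
            for m in net.modules()
            if isinstance(m, (nn.Conv3d, nn.ConvTranspose3d))
        )

    w8, w16 = conv_weights(8), conv_weights(16)
    assert w16 == pytest.approx(4 * w8, rel=0.10)


def test_gradient_reaches_every_parameter(rng):
    net = build_network(NetworkConfig(levels=2, base_width=4), seed=0)
    x = rng.normal(0, 1, (2, 1, 4, 4, 4)).astype("f4")
    out = net(x)
    loss = ((out - 0.3) ** 2.0).mean()
    net.zero_grad()
    loss.backward()
    for name, p in net.named_parameters():
        assert p.grad is not None and np.linalg.norm(p.grad) > 0, name


def test_forward_deterministic_with_fixed_weights(rng):
    net = build_network(DESK, seed=3)
    x = rng.normal(0, 1, (1, 1, 8, 8, 8)).astype("f4")
    np.testing.assert_array_equal(net(x).data, net(x).data)
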