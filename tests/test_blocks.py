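"""CSEA building-block checks against straight-line and brute-force oracles."""

import numpy as np
import pytest

from cseanet import CERM, SFEM, DCSE, CoordinateAttention, CSEABlock, ca_pool
from cseanet.engine import Tensor, no_grad
from cseanet.errors import ConfigurationError


def _zero_branches(module):
    """Zero every conv weight in a (sub)module tree."""
    for p in module.parameters():
        p.data[...] = 0.0


# -- CERM -----------------------------------------------------------------


@pytest.mark.parametrize("channels", [16, 24, 32, 64])
def test_cerm_channel_split_is_exact(channels):
    m = CERM(channels, np.random.default_rng(0))
    assert sum(m.branch_channels) == channels
    assert m.branch_channels == (channels // 8, channels // 4, 5 * channels // 8)


def test_cerm_rejects_indivisible_channel_count():
    with pytest.raises(ConfigurationError, match="12"):
        CERM(12, np.random.default_rng(0))


def test_cerm_zeroed_branches_reduce_to_identity(rng):
    m = CERM(16, np.random.default_rng(1))
    _zero_branches(m.branch1)
    _zero_branches(m.branch2)
    _zero_branches(m.branch3)
    x = rng.normal(size=(2, 16, 10, 10)).astype(np.float32)
    with no_grad():
        y = m(Tensor(x)).data
    np.testing.assert_allclose(y, x, atol=1e-6)


def _conv_bn_relu_reference(x, seq, training=True):
    """Straight-line numpy re-implementation of conv+BN+ReLU with the same weights."""
    conv, bn = seq.layers[0], seq.layers[1]
    w = conv.weight.data
    O, C, kh, kw = w.shape
    p, d = conv.padding, conv.dilation
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    OH = x.shape[2] + 2 * p - d * (kh - 1)
    OW = x.shape[3] + 2 * p - d * (kw - 1)
    y = np.zeros((x.shape[0], O, OH, OW))
    for b in range(x.shape[0]):
        for o in range(O):
            for c in range(C):
                for i in range(kh):
                    for j in range(kw):
                        y[b, o] += w[o, c, i, j] * xp[b, c, i * d : i * d + OH, j * d : j * d + OW]
    mu = y.mean(axis=(0, 2, 3), keepdims=True)
    var = y.var(axis=(0, 2, 3), keepdims=True)
    yh = (y - mu) / np.sqrt(var + bn.eps)
    yh = bn.gamma.data.reshape(1, -1, 1, 1) * yh + bn.beta.data.reshape(1, -1, 1, 1)
    if len(seq.layers) > 2:
        yh = np.maximum(yh, 0.0)
    return yh


def test_cerm_matches_straight_line_reference(rng):
    m = CERM(32, np.random.default_rng(2))
    x = rng.normal(size=(2, 32, 8, 8)).astype(np.float32)
    y = m(Tensor(x)).data  # training-mode BN, matching the reference
    x1 = _conv_bn_relu_reference(x, m.trunk)
    parts = [_conv_bn_relu_reference(x1, b) for b in (m.branch1, m.branch2, m.branch3)]
    ref = x + np.concatenate(parts, axis=1)
    np.testing.assert_allclose(y, ref, rtol=1e-4, atol=1e-4)


# -- SFEM -----------------------------------------------------------------


def test_sfem_effective_receptive_fields():
    assert [SFEM.effective_kernel(3, r) for r in (3, 5, 7)] == [7, 11, 15]


def test_sfem_preserves_shape(rng):
    m = SFEM(16, np.random.default_rng(3))
    x = rng.normal(size=(1, 16, 33, 47)).astype(np.float32)
    with no_grad():
        assert m(Tensor(x)).shape == (1, 16, 33, 47)


def test_sfem_dilated_branch_support_matches_dilation():
    """An impulse through one dilated conv spreads exactly to the effective kernel."""
    m = SFEM(8, np.random.default_rng(4))
    conv = m.dilated2.layers[0]  # dilation 7
    x = np.zeros((1, 8, 31, 31), dtype=np.float32)
    x[0, 0, 15, 15] = 1.0
    from cseanet.engine import conv2d

    with no_grad():
        y = conv2d(Tensor(x), conv.weight, padding=conv.padding, dilation=conv.dilation).data
    nz = np.argwhere(np.abs(y[0]).max(axis=0) > 0)
    extent = nz.max(axis=0) - nz.min(axis=0) + 1
    assert tuple(extent) == (15, 15) == (SFEM.effective_kernel(3, 7),) * 2


# -- DCSE -----------------------------------------------------------------


def test_dcse_concatenation_carries_double_channels(rng, monkeypatch):
    m = DCSE(32, np.random.default_rng(5))
    x = Tensor(rng.normal(size=(2, 32, 12, 12)).astype(np.float32))
    seen = {}
    original = m.fuse.forward

    def spy(t):
        seen["channels"] = t.shape[1]
        return original(t)

    monkeypatch.setattr(m.fuse, "forward", spy)
    with no_grad():
        y = m(x)
    assert seen["channels"] == 64  # C (CERM) + C (SFEM)
    assert y.shape == (2, 32, 12, 12)


def test_dcse_zeroed_branches_pass_residual_through_fusion(rng):
    """With every branch conv zeroed except the CERM residual path, the DCSE
    output equals fusion(Concat(x, 0)) computed by a straight-line oracle."""
    m = DCSE(16, np.random.default_rng(6))
    _zero_branches(m.cerm.branch1)
    _zero_branches(m.cerm.branch2)
    _zero_branches(m.cerm.branch3)
    _zero_branches(m.sfem.fuse)
    x = rng.normal(size=(1, 16, 6, 6)).astype(np.float32)
    y = m(Tensor(x)).data
    ref = _conv_bn_relu_reference(np.concatenate([x, np.zeros_like(x)], axis=1), m.fuse)
    np.testing.assert_allclose(y, ref, rtol=1e-4, atol=1e-4)


# -- coordinate attention -------------------------------------------------


def test_ca_pool_constant_input():
    z_h, z_w = ca_pool(np.full((1, 2, 4, 5), 3.25))
    np.testing.assert_allclose(z_h, 3.25)
    np.testing.assert_allclose(z_w, 3.25)


def test_ca_pool_hand_example():
    x = np.array([[[[1.0, 3.0], [5.0, 7.0]]]])
    z_h, z_w = ca_pool(x)
    np.testing.assert_allclose(z_h[0, 0], [2.0, 6.0])  # row means
    np.testing.assert_allclose(z_w[0, 0], [3.0, 5.0])  # column means


def test_ca_pool_singleton_axes(rng):
    row = rng.normal(size=(1, 3, 1, 6))
    z_h, z_w = ca_pool(row)
    np.testing.assert_allclose(z_w[..., :], row[:, :, 0, :])
    col = rng.normal(size=(1, 3, 6, 1))
    z_h, z_w = ca_pool(col)
    np.testing.assert_allclose(z_h, col[:, :, :, 0])


def test_ca_pool_matches_naive_loops(rng):
    for _ in range(50):
        B, C, H, W = rng.integers(1, 4), rng.integers(1, 5), rng.integers(1, 7), rng.integers(1, 7)
        x = rng.normal(size=(B, C, H, W))
        z_h, z_w = ca_pool(x)
        for b in range(B):
            for c in range(C):
                for h in range(H):
                    assert abs(z_h[b, c, h] - sum(x[b, c, h, i] for i in range(W)) / W) < 1e-6
                for w in range(W):
                    assert abs(z_w[b, c, w] - sum(x[b, c, j, w] for j in range(H)) / H) < 1e-6


def test_ca_forward_matches_per_pixel_gating_loop(rng):
    ca = CoordinateAttention(16, np.random.default_rng(7))
    x = rng.normal(size=(1, 16, 7, 9)).astype(np.float32)
    xt = Tensor(x)
    with no_grad():
        gh, gw = ca.gates(xt)
        u = ca(xt).data
    ref = np.zeros_like(x)
    for c in range(16):
        for i in range(7):
            for j in range(9):
                ref[0, c, i, j] = x[0, c, i, j] * gh.data[0, c, i, 0] * gw.data[0, c, 0, j]
    np.testing.assert_allclose(u, ref, atol=1e-5)


def test_ca_gates_bounded_in_unit_interval(rng):
    ca = CoordinateAttention(16, np.random.default_rng(8), dtype=np.float64)
    with no_grad():
        gh, gw = ca.gates(Tensor(rng.normal(size=(2, 16, 5, 5)) * 5.0))
    for g in (gh.data, gw.data):
        assert np.all(g > 0.0) and np.all(g < 1.0)


def test_ca_with_gates_forced_open_is_identity(rng):
    ca = CoordinateAttention(16, np.random.default_rng(9))
    for conv in (ca.expand_h, ca.expand_w):
        conv.weight.data[...] = 0.0
        conv.bias.data[...] = 40.0  # sigmoid(40) rounds to 1.0 in float32
    x = rng.normal(size=(2, 16, 6, 8)).astype(np.float32)
    with no_grad():
        y = ca(Tensor(x)).data
    np.testing.assert_allclose(y, x, atol=1e-6)


def test_ca_rejects_channel_mismatch(rng):
    ca = CoordinateAttention(16, np.random.default_rng(10))
    with pytest.raises(ConfigurationError, match="C=16"):
        with no_grad():
            ca(Tensor(np.zeros((1, 8, 4, 4), dtype=np.float32)))


def test_ca_squeeze_width_floor():
    assert CoordinateAttention(16, np.random.default_rng(0), reduction=32).mid_channels == 8
    assert CoordinateAttention(512, np.random.default_rng(0), reduction=32).mid_channels == 16


# -- CSEA -----------------------------------------------------------------


@pytest.mark.parametrize("channels", [16, 24, 32, 64])
def test_all_blocks_preserve_shape(channels, rng):
    x = Tensor(rng.normal(size=(2, channels, 10, 12)).astype(np.float32))
    for cls in (CERM, SFEM, DCSE, CoordinateAttention, CSEABlock):
        m = cls(channels, np.random.default_rng(channels))
        with no_grad():
            assert m(x).shape == x.shape, cls.__name__


def test_csea_is_composition_of_its_stages(rng):
    block = CSEABlock(16, np.random.default_rng(11))
    x = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
    with no_grad():
        whole = block(x).data
        staged = block.dcse2(block.ca(block.dcse1(x))).data
    np.testing.assert_allclose(whole, staged, atol=1e-6)


def test_csea_has_parameters_unlike_identity_skip():
    block = CSEABlock(32, np.random.default_rng(12))
    assert sum(p.data.size for p in block.parameters()) > 0


def test_csea_gradient_matches_finite_differences(rng):
    block = CSEABlock(8, np.random.default_rng(13), dtype=np.float64)
    x = rng.normal(size=(1, 8, 6, 6))
    cw = rng.normal(size=(1, 8, 6, 6))

    xt = Tensor(x, requires_grad=True)
    (block(xt) * Tensor(cw)).sum().backward()

    def f(xv):
        with no_grad():
            return float((block(Tensor(xv)).data * cw).sum())

    h = 1e-6
    for _ in range(25):
        idx = tuple(rng.integers(s) for s in x.shape)
        xp, xm = x.copy(), x.copy()
        xp[idx] += h
        xm[idx] -= h
        num = (f(xp) - f(xm)) / (2 * h)
        assert abs(num - xt.grad[idx]) < 1e-3 * max(1.0, abs(num))
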