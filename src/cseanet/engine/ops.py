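"""Convolution, pooling and upsampling primitives with hand-written gradients.

``conv2d`` lowers to a single im2col GEMM per pass; the patch matrix is
rebuilt during backward rather than kept on the graph, which bounds peak
memory. Stride is fixed at 1 (the network downsamples with max-pooling, not
strided convolution); dilation is supported because the spatial-enhancement
branch needs rates 3/5/7.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _from_op


def _im2col(xp: np.ndarray, kh: int, kw: int, d: int, OH: int, OW: int) -> np.ndarray:
    """Patch matrix (B, C*kh*kw, OH*OW); tap order matches w.reshape(O, -1)."""
    B, C = xp.shape[:2]
    cols = np.empty((B, C, kh * kw, OH, OW), dtype=xp.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j] = xp[:, :, i * d : i * d + OH, j * d : j * d + OW]
    return cols.reshape(B, C * kh * kw, OH * OW)


def conv2d(x: Tensor, w: Tensor, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation, stride 1, as one im2col GEMM. x: (B,C,H,W); w: (O,C,kh,kw).

    The patch matrix is rebuilt in the backward pass instead of being kept
    alive on the graph, trading a cheap re-slice for a large memory saving.
    """
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, C2, kh, kw = wd.shape
    if C != C2:
        raise ValueError(f"conv2d: input has {C} channels, kernel expects {C2}")
    p, d = int(padding), int(dilation)
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    OH = H + 2 * p - d * (kh - 1)
    OW = W + 2 * p - d * (kw - 1)
    if OH < 1 or OW < 1:
        raise ValueError(f"conv2d: kernel {kh}x{kw} (dilation {d}) exceeds padded input")

    w2 = wd.reshape(O, C * kh * kw)
    if kh == kw == 1:
        out_data = np.matmul(w2, xp.reshape(B, C, H * W)).reshape(B, O, OH, OW)
    else:
        cols = _im2col(xp, kh, kw, d, OH, OW)
        out_data = np.matmul(w2, cols).reshape(B, O, OH, OW)
        del cols

    def bw(g):
        g2 = g.reshape(B, O, OH * OW)
        need_x = x.requires_grad or x._parents
        if kh == kw == 1:
            if w.requires_grad or w._parents:
                xflat = xp.reshape(B, C, H * W)
                gw = np.einsum("bop,bcp->oc", g2, xflat, optimize=True)
                w._accumulate(gw.reshape(wd.shape))
            if need_x:
                gx = np.matmul(w2.T, g2).reshape(B, C, H, W)
                x._accumulate(gx)
            return
        cols = _im2col(xp, kh, kw, d, OH, OW)
        if w.requires_grad or w._parents:
            gw = np.einsum("bop,bkp->ok", g2, cols, optimize=True)
            w._accumulate(gw.reshape(wd.shape))
        if need_x:
            dcols = np.matmul(w2.T, g2).reshape(B, C, kh * kw, OH, OW)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i * d : i * d + OH, j * d : j * d + OW] += dcols[:, :, i * kw + j]
            gx = gxp[:, :, p : p + H, p : p + W] if p else gxp
            x._accumulate(gx)

    return _from_op(out_data, (x, w), bw)


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max-pooling, stride 2; H and W must be even."""
    xd = x.data
    B, C, H, W = xd.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2d: spatial dims ({H}, {W}) must be even")
    xr = xd.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = np.ascontiguousarray(xr).reshape(B, C, H // 2, W // 2, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(np.ascontiguousarray(gx).reshape(B, C, H, W))

    return _from_op(out_data, (x,), bw)


_UP_CACHE: dict = {}


def _up_matrix(n: int, dtype) -> np.ndarray:
    """(2n, n) interpolation matrix for bilinear x2 (half-pixel alignment)."""
    key = (n, np.dtype(dtype).str)
    if key not in _UP_CACHE:
        A = np.zeros((2 * n, n), dtype=dtype)
        src = np.clip((np.arange(2 * n) + 0.5) / 2.0 - 0.5, 0.0, n - 1.0)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n - 1)
        frac = (src - i0).astype(dtype)
        rows = np.arange(2 * n)
        np.add.at(A, (rows, i0), 1.0 - frac)
        np.add.at(A, (rows, i1), frac)
        _UP_CACHE[key] = A
    return _UP_CACHE[key]


def upsample_bilinear2x(x: Tensor) -> Tensor:
    """Bilinear x2 upsampling expressed as two separable matrix products."""
    xd = x.data
    B, C, H, W = xd.shape
    Ah = _up_matrix(H, xd.dtype)
    Aw = _up_matrix(W, xd.dtype)
    tmp = np.tensordot(xd, Aw, axes=([3], [1]))          # (B, C, H, 2W)
    out_data = np.tensordot(tmp, Ah, axes=([2], [1]))    # (B, C, 2W, 2H)
    out_data = np.ascontiguousarray(out_data.transpose(0, 1, 3, 2))

    def bw(g):
        t = np.tensordot(g, Ah, axes=([2], [0]))         # (B, C, 2W, H)
        t = t.transpose(0, 1, 3, 2)                      # (B, C, H, 2W)
        gx = np.tensordot(t, Aw, axes=([3], [0]))        # (B, C, H, W)
        x._accumulate(np.ascontiguousarray(gx))

    return _from_op(out_data, (x,), bw)


def batchnorm2d_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch norm over (B, H, W) per channel.

    Returns (out, batch_mean, batch_var) with the biased batch variance;
    the backward pass uses the closed-form batch-norm gradient, which is
    cheaper than differentiating through the moment computations op by op.
    """
    xd = x.data
    B, C, H, W = xd.shape
    N = B * H * W
    mu = xd.mean(axis=(0, 2, 3))
    var = xd.var(axis=(0, 2, 3))
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, C, 1, 1)) * inv_std.reshape(1, C, 1, 1)
    out_data = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        dbeta = g.sum(axis=(0, 2, 3))
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        if gamma.requires_grad or gamma._parents:
            gamma._accumulate(dgamma)
        if beta.requires_grad or beta._parents:
            beta._accumulate(dbeta)
        if x.requires_grad or x._parents:
            coef = (gamma.data * inv_std).reshape(1, C, 1, 1)
            gx = coef * (g - (dbeta / N).reshape(1, C, 1, 1)
                         - xhat * (dgamma / N).reshape(1, C, 1, 1))
            x._accumulate(gx.astype(xd.dtype, copy=False))

    return _from_op(out_data, (x, gamma, beta), bw), mu, var
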