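"""Channel-spatial enhanced attention (CSEA) building blocks.

A CSEA block is the skip-connection replacement used by the segmentation
network: two dual-branch channel-spatial feature-enhancement (DCSE) modules
wrapped around a coordinate-attention (CA) gate,

    CSEA(x) = DCSE2( CA( DCSE1(x) ) ).

Each DCSE fuses two parallel views of its input:

* **CERM** (channel-enhanced residual module) — a 3x3 trunk convolution
  followed by three parallel 3x3 convolutions with filter counts C/8, C/4
  and 5C/8 (so the concatenation restores exactly C channels), added back
  to the input residually. The uneven channel split diversifies the channel
  statistics the block can represent.
* **SFEM** (spatial feature-enhancement module) — a 1x1 entry convolution
  followed by three parallel 3x3 dilated convolutions at rates 3, 5 and 7
  (effective kernels 7, 11 and 15 pixels), concatenated and fused back to C
  channels by a 1x1 convolution. The growing dilation widens the receptive
  field so low-contrast nodule contours are seen in context.

Coordinate attention pools the feature map separately along rows and
columns, squeezes the two direction-aware profiles through a shared 1x1
convolution, and emits per-row and per-column sigmoid gates whose outer
product rescales the feature map: u_c(i, j) = y_c(i, j) * g^h_c(i) * g^w_c(j).

All blocks preserve the (B, C, H, W) shape, which is what lets them stand in
for an identity skip connection.
"""

from __future__ import annotations

import numpy as np

from . import engine as E
from .engine import nn
from .engine.tensor import Tensor
from .errors import ConfigurationError

CERM_ALPHA = 8  # channel split denominator: branches C/8, 2C/8, 5C/8


def _check_divisible(channels: int) -> None:
    if channels % CERM_ALPHA != 0:
        raise ConfigurationError(
            f"CERM requires the channel count to be divisible by {CERM_ALPHA} "
            f"so the 1/8-1/4-5/8 split is integral; got C={channels}"
        )


class CERM(nn.Module):
    """Channel-enhanced residual module.

    y1 = x + Concat(F(x1, C/8), F(x1, C/4), F(x1, 5C/8)) with x1 = F(x, C),
    every F a 3x3 convolution + batch norm + ReLU.
    """

    def __init__(self, channels: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        _check_divisible(channels)
        self.channels = channels
        a = channels // CERM_ALPHA
        self.branch_channels = (a, 2 * a, 5 * a)
        self.trunk = nn.conv_bn_act(channels, channels, 3, rng, dtype=dtype)
        self.branch1 = nn.conv_bn_act(channels, a, 3, rng, dtype=dtype)
        self.branch2 = nn.conv_bn_act(channels, 2 * a, 3, rng, dtype=dtype)
        self.branch3 = nn.conv_bn_act(channels, 5 * a, 3, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x1 = self.trunk(x)
        enriched = E.concat([self.branch1(x1), self.branch2(x1), self.branch3(x1)], axis=1)
        return x + enriched


class SFEM(nn.Module):
    """Spatial feature-enhancement module with parallel dilated convolutions.

    Each dilated 3x3 branch keeps C channels and pads by its dilation rate so
    the spatial shape is preserved; a trailing 1x1 convolution fuses the
    3C-channel concatenation back to C.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 dilations: tuple[int, ...] = (3, 5, 7), dtype=None):
        super().__init__()
        self.channels = channels
        self.dilations = tuple(dilations)
        self.entry = nn.conv_bn_act(channels, channels, 1, rng, dtype=dtype)
        for k, r in enumerate(self.dilations):
            setattr(self, f"dilated{k}",
                    nn.conv_bn_act(channels, channels, 3, rng, dilation=r, dtype=dtype))
        self.fuse = nn.conv_bn_act(len(self.dilations) * channels, channels, 1, rng,
                                   act=False, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x1 = self.entry(x)
        branches = [getattr(self, f"dilated{k}")(x1) for k in range(len(self.dilations))]
        return self.fuse(E.concat(branches, axis=1))

    @staticmethod
    def effective_kernel(kernel: int, dilation: int) -> int:
        """Effective receptive field of one dilated tap: k + (k-1)(r-1)."""
        return kernel + (kernel - 1) * (dilation - 1)


class DCSE(nn.Module):
    """Dual-branch channel-spatial feature enhancement: fuse(Concat(CERM(x), SFEM(x))).

    The concatenation carries 2C channels; a 1x1 fusion convolution returns to
    C so the module is channel-preserving.
    """

    def __init__(self, channels: int, rng: np.random.Generator, dtype=None):
        super().__init__()
        _check_divisible(channels)
        self.channels = channels
        self.cerm = CERM(channels, rng, dtype=dtype)
        self.sfem = SFEM(channels, rng, dtype=dtype)
        self.fuse = nn.conv_bn_act(2 * channels, channels, 1, rng, act=False, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.fuse(E.concat([self.cerm(x), self.sfem(x)], axis=1))


def ca_pool(y) -> tuple[np.ndarray, np.ndarray]:
    """Directional pooling: per-row means z^h (B, C, H) and per-column means z^w (B, C, W)."""
    data = y.data if isinstance(y, Tensor) else np.asarray(y)
    return data.mean(axis=3), data.mean(axis=2)


class CoordinateAttention(nn.Module):
    """Coordinate attention: factorized row/column gates.

    The row profile z^h (width-axis mean) and column profile z^w (height-axis
    mean) are concatenated along the spatial axis, squeezed to
    max(ceil(C/r), 8) channels by a 1x1 convolution + batch norm + hard-swish,
    split back into the two directions, expanded to C channels and passed
    through sigmoids. The input is rescaled by the outer product of the two
    gate vectors per channel.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 32, min_mid_channels: int = 8, dtype=None):
        super().__init__()
        self.channels = channels
        self.reduction = reduction
        mid = max(int(np.ceil(channels / reduction)), min_mid_channels)
        self.mid_channels = mid
        self.squeeze = nn.Sequential(
            nn.Conv2d(channels, mid, 1, rng, bias=False, dtype=dtype),
            nn.BatchNorm2d(mid, dtype=dtype),
            nn.HardSwish(),
        )
        self.expand_h = nn.Conv2d(mid, channels, 1, rng, dtype=dtype)
        self.expand_w = nn.Conv2d(mid, channels, 1, rng, dtype=dtype)

    def gates(self, y: Tensor) -> tuple[Tensor, Tensor]:
        """Return (g^h, g^w) shaped (B, C, H, 1) and (B, C, 1, W)."""
        if y.data.shape[1] != self.channels:
            raise ConfigurationError(
                f"coordinate attention built for C={self.channels} "
                f"got input with C={y.data.shape[1]}"
            )
        B, C, H, W = y.data.shape
        zh = y.mean(axis=3)                      # (B, C, H)
        zw = y.mean(axis=2)                      # (B, C, W)
        z = E.concat([zh, zw], axis=2)           # (B, C, H+W)
        f = self.squeeze(z.reshape(B, C, H + W, 1))
        fh = f[:, :, :H, :]                      # (B, mid, H, 1)
        fw = f[:, :, H:, :]                      # (B, mid, W, 1)
        gh = E.sigmoid(self.expand_h(fh))        # (B, C, H, 1)
        gw = E.sigmoid(self.expand_w(fw)).reshape(B, C, 1, W)
        return gh, gw

    def forward(self, y: Tensor) -> Tensor:
        gh, gw = self.gates(y)
        return y * gh * gw


class CSEABlock(nn.Module):
    """DCSE -> coordinate attention -> DCSE; a drop-in skip-connection module."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 ca_reduction: int = 32, dtype=None):
        super().__init__()
        _check_divisible(channels)
        self.channels = channels
        self.dcse1 = DCSE(channels, rng, dtype=dtype)
        self.ca = CoordinateAttention(channels, rng, reduction=ca_reduction, dtype=dtype)
        self.dcse2 = DCSE(channels, rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.dcse2(self.ca(self.dcse1(x)))
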