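"""Nested encoder-decoder (U-Net++) segmentation network with CSEA skips.

The encoder is a column of convolutional stages X(i, 0); the decoder is the
dense upper-triangular grid of U-Net++ nodes X(i, j), each receiving every
earlier node of its level plus an upsampled feature from the level below:

    X(i, j) = block( Concat[ S_i, X(i, 1), ..., X(i, j-1), Up(X(i+1, j-1)) ] )

where S_i is the skip transform of encoder output X(i, 0). ``skip_mode``
selects that transform — identity (plain U-Net++), a single DCSE, a single
coordinate-attention module, or the full CSEA block — which is the ablation
axis of the model family. The default placement applies one skip module per
encoder level (shared by all nested nodes of that level); ``per_edge``
instantiates an independent module for every dense connection.

The head is a 1x1 convolution to one channel; ``forward`` returns sigmoid
probabilities, ``forward(x, logits=True)`` returns pre-sigmoid scores for
numerically stable loss evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import engine as E
from .blocks import CSEABlock, CoordinateAttention, DCSE
from .engine import nn
from .engine.tensor import Tensor
from .errors import ConfigurationError, ShapeError

SKIP_MODES = ("plain", "dcse_only", "ca_only", "csea")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    depth: number of encoder levels; the bottleneck sits at level depth-1.
    base_channels: channel width at level 0, doubled per level; must be a
        multiple of 8 so the CERM channel split stays integral.
    skip_mode: skip-connection transform (the ablation axis).
    csea_placement: 'per_level' shares one skip module per encoder level;
        'per_edge' builds one per dense connection.
    """

    depth: int = 5
    base_channels: int = 32
    input_channels: int = 3
    output_channels: int = 1
    skip_mode: str = "csea"
    csea_placement: str = "per_level"
    deep_supervision: bool = False
    ca_reduction: int = 32
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if self.skip_mode not in SKIP_MODES:
            raise ConfigurationError(f"skip_mode must be one of {SKIP_MODES}, got {self.skip_mode!r}")
        if self.csea_placement not in ("per_level", "per_edge"):
            raise ConfigurationError(f"csea_placement must be per_level or per_edge, got {self.csea_placement!r}")
        if self.base_channels % 8 != 0 or self.base_channels < 8:
            raise ConfigurationError(
                f"base_channels must be a positive multiple of 8, got {self.base_channels}"
            )
        if self.depth < 2:
            raise ConfigurationError(f"depth must be >= 2, got {self.depth}")

    @property
    def level_channels(self) -> list[int]:
        return [self.base_channels * (2 ** i) for i in range(self.depth)]

    @property
    def spatial_divisor(self) -> int:
        return 2 ** (self.depth - 1)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


def _stage(in_ch: int, out_ch: int, rng, dtype) -> nn.Sequential:
    """Two 3x3 conv + BN + ReLU layers — the standard encoder/decoder node."""
    return nn.Sequential(
        nn.conv_bn_act(in_ch, out_ch, 3, rng, dtype=dtype),
        nn.conv_bn_act(out_ch, out_ch, 3, rng, dtype=dtype),
    )


def _make_skip(mode: str, channels: int, rng, ca_reduction: int, dtype) -> nn.Module:
    if mode == "plain":
        return nn.Identity()
    if mode == "dcse_only":
        return DCSE(channels, rng, dtype=dtype)
    if mode == "ca_only":
        return CoordinateAttention(channels, rng, reduction=ca_reduction, dtype=dtype)
    return CSEABlock(channels, rng, ca_reduction=ca_reduction, dtype=dtype)


class SegmentationModel(nn.Module):
    """U-Net++ with configurable skip transforms (see module docstring)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        dtype = np.dtype(cfg.dtype).type
        chans = cfg.level_channels
        D = cfg.depth

        # encoder column X(i, 0)
        for i in range(D):
            in_ch = cfg.input_channels if i == 0 else chans[i - 1]
            setattr(self, f"enc{i}", _stage(in_ch, chans[i], rng, dtype))
        self.pool = nn.MaxPool2d()
        self.up = nn.UpsampleBilinear2x()

        # skip transforms (levels 0..D-2 feed nested nodes)
        for i in range(D - 1):
            if cfg.csea_placement == "per_level":
                setattr(self, f"skip{i}",
                        _make_skip(cfg.skip_mode, chans[i], rng, cfg.ca_reduction, dtype))
            else:
                for j in range(1, D - i):
                    setattr(self, f"skip{i}_{j}",
                            _make_skip(cfg.skip_mode, chans[i], rng, cfg.ca_reduction, dtype))

        # upsample projections and nested decoder nodes X(i, j), j >= 1
        for i in range(D - 1):
            for j in range(1, D - i):
                setattr(self, f"upconv{i}_{j}",
                        nn.conv_bn_act(chans[i + 1], chans[i], 3, rng, dtype=dtype))
                in_ch = chans[i] * (j + 1)
                setattr(self, f"node{i}_{j}", _stage(in_ch, chans[i], rng, dtype))

        if cfg.deep_supervision:
            for j in range(1, D):
                setattr(self, f"head{j}",
                        nn.Conv2d(chans[0], cfg.output_channels, 1, rng, dtype=dtype))
        else:
            self.head = nn.Conv2d(chans[0], cfg.output_channels, 1, rng, dtype=dtype)

    # -- forward ----------------------------------------------------------

    def forward(self, x, logits: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.cfg.dtype))
        B, C, H, W = x.data.shape
        cfg = self.cfg
        if C != cfg.input_channels:
            raise ShapeError(f"expected {cfg.input_channels} input channels, got {C}")
        div = cfg.spatial_divisor
        if H % div or W % div:
            raise ConfigurationError(
                f"input spatial dims ({H}, {W}) must be divisible by {div} for depth {cfg.depth}"
            )
        D = cfg.depth
        grid: dict[tuple[int, int], Tensor] = {}
        feat = x
        for i in range(D):
            feat = getattr(self, f"enc{i}")(feat if i == 0 else self.pool(grid[(i - 1, 0)]))
            grid[(i, 0)] = feat

        def skip_of(i: int, j: int) -> Tensor:
            if cfg.csea_placement == "per_level":
                key = (i, "skip")
                if key not in grid:
                    grid[key] = getattr(self, f"skip{i}")(grid[(i, 0)])
                return grid[key]
            return getattr(self, f"skip{i}_{j}")(grid[(i, 0)])

        for j in range(1, D):
            for i in range(D - j):
                below = getattr(self, f"upconv{i}_{j}")(self.up(grid[(i + 1, j - 1)]))
                inputs = [skip_of(i, j)]
                inputs += [grid[(i, k)] for k in range(1, j)]
                inputs.append(below)
                grid[(i, j)] = getattr(self, f"node{i}_{j}")(E.concat(inputs, axis=1))

        if cfg.deep_supervision:
            outs = [getattr(self, f"head{j}")(grid[(0, j)]) for j in range(1, D)]
            z = outs[0]
            for o in outs[1:]:
                z = z + o
            z = z * (1.0 / len(outs))
        else:
            z = self.head(grid[(0, D - 1)])
        return z if logits else E.sigmoid(z)


def build_model(cfg: ModelConfig) -> SegmentationModel:
    """Deterministically construct a model from its configuration."""
    return SegmentationModel(cfg)


def count_parameters(model: nn.Module) -> int:
    """Total learnable scalar count."""
    return int(sum(p.data.size for p in model.parameters()))
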