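"""Layer library: Module base class, convolution, batch norm, activations.

Initialization is He (fan-in) normal, drawn from a generator that the model
builder threads through every layer in construction order, so a model built
twice from the same seed has identical weights.
"""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .ops import batchnorm2d_train, conv2d, maxpool2d, upsample_bilinear2x
from .tensor import Tensor


class Parameter(Tensor):
    def __init__(self, data, dtype=None):
        super().__init__(np.asarray(data), requires_grad=True, dtype=dtype)


class Module:
    """Minimal module container with recursive parameter/state traversal."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        state = {f"param.{k}": p.data for k, p in self.named_parameters()}
        state.update({f"buffer.{k}": b for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        for key, arr in state.items():
            kind, _, name = key.partition(".")
            if kind == "param":
                p = params[name]
                if p.data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for {name}: {p.data.shape} vs {arr.shape}")
                p.data = arr.astype(p.data.dtype, copy=True)
            elif kind == "buffer":
                obj = self
                *path, leaf = name.split(".")
                for part in path:
                    obj = obj._modules[part]
                obj._set_buffer(leaf, arr.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"_{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    """3x3/1x1 convolution with optional dilation; 'same' padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, padding: int | None = None,
                 dilation: int = 1, bias: bool = True, dtype=None):
        super().__init__()
        dtype = dtype or T.DEFAULT_DTYPE
        k = kernel_size
        if padding is None:
            padding = dilation * (k - 1) // 2
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.padding, self.dilation = k, padding, dilation
        fan_in = in_channels * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, std, size=(out_channels, in_channels, k, k)), dtype=dtype)
        self.bias = Parameter(np.zeros(out_channels), dtype=dtype) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = conv2d(x, self.weight, padding=self.padding, dilation=self.dilation)
        if self.bias is not None:
            y = y + self.bias.reshape(1, self.out_channels, 1, 1)
        return y


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel.

    Training mode normalizes with batch statistics (gradients flow through
    them); evaluation mode uses the tracked running moments.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1, dtype=None):
        super().__init__()
        dtype = dtype or T.DEFAULT_DTYPE
        self.channels, self.eps, self.momentum = channels, eps, momentum
        self.gamma = Parameter(np.ones(channels), dtype=dtype)
        self.beta = Parameter(np.zeros(channels), dtype=dtype)
        self.register_buffer("running_mean", np.zeros(channels, dtype=dtype))
        self.register_buffer("running_var", np.ones(channels, dtype=dtype))

    def forward(self, x: Tensor) -> Tensor:
        C = self.channels
        if self.training:
            out, mu, var = batchnorm2d_train(x, self.gamma, self.beta, self.eps)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            m = self.momentum
            self._set_buffer("running_mean",
                             ((1 - m) * self.running_mean + m * mu).astype(self.running_mean.dtype))
            self._set_buffer("running_var",
                             ((1 - m) * self.running_var + m * var * unbias).astype(self.running_var.dtype))
            return out
        mu = self.running_mean.reshape(1, C, 1, 1)
        sd = np.sqrt(self.running_var.reshape(1, C, 1, 1) + self.eps)
        xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return self.gamma.reshape(1, C, 1, 1) * xhat + self.beta.reshape(1, C, 1, 1)


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)


class HardSwish(Module):
    def forward(self, x):
        return T.hardswish(x)


class MaxPool2d(Module):
    def forward(self, x):
        return maxpool2d(x)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return upsample_bilinear2x(x)


def conv_bn_act(in_ch: int, out_ch: int, kernel_size: int, rng: np.random.Generator,
                dilation: int = 1, act: bool = True, dtype=None) -> Sequential:
    """Conv -> BatchNorm -> (ReLU); fusion 1x1 convs set act=False."""
    layers = [
        Conv2d(in_ch, out_ch, kernel_size, rng, dilation=dilation, bias=False, dtype=dtype),
        BatchNorm2d(out_ch, dtype=dtype),
    ]
    if act:
        layers.append(ReLU())
    return Sequential(*layers)
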