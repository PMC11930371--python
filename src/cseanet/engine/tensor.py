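"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a numpy ``ndarray`` and, when gradients are enabled,
records the operations applied to it so that :meth:`Tensor.backward` can
propagate gradients to every tensor created with ``requires_grad=True``.
The op set is the minimum needed by a convolutional segmentation network:
broadcasting arithmetic, the usual activations, axis reductions, reshaping,
slicing, concatenation, and (in :mod:`cseanet.engine.ops`) convolution,
pooling and bilinear upsampling.

Gradients accumulate: a tensor used twice receives the sum of both
contributions, which is what makes residual additions and batch-norm's
repeated use of the input come out right.
"""

from __future__ import annotations

import numpy as np

DEFAULT_DTYPE = np.float32

_GRAD_ENABLED = True


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        if dtype is not None:
            arr = arr.astype(dtype, copy=False)
        elif not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(DEFAULT_DTYPE)
        self.data = arr
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and (p.requires_grad or p._parents):
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- op construction helper ------------------------------------------


def _as_tensor(x, like: Tensor | None = None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    dtype = like.data.dtype if like is not None else None
    return Tensor(np.asarray(x, dtype=dtype))


def _from_op(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# -- arithmetic ----------------------------------------------------------


def _add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _from_op(a.data + b.data, (a, b), bw)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _from_op(a.data * b.data, (a, b), bw)


def _sub(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return _from_op(a.data - b.data, (a, b), bw)


def _div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        if a.requires_grad or a._parents:
            a._accumulate(_unbroadcast(g / b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _from_op(a.data / b.data, (a, b), bw)


def _method(op):
    def fn(self, other):
        return op(self, _as_tensor(other, like=self))

    return fn


def _rmethod(op):
    def fn(self, other):
        return op(_as_tensor(other, like=self), self)

    return fn


Tensor.__add__ = _method(_add)
Tensor.__radd__ = _rmethod(_add)
Tensor.__sub__ = _method(_sub)
Tensor.__rsub__ = _rmethod(_sub)
Tensor.__mul__ = _method(_mul)
Tensor.__rmul__ = _rmethod(_mul)
Tensor.__truediv__ = _method(_div)
Tensor.__rtruediv__ = _rmethod(_div)


def _neg(self: Tensor) -> Tensor:
    def bw(g):
        self._accumulate(-g)

    return _from_op(-self.data, (self,), bw)


Tensor.__neg__ = _neg


def _pow(self: Tensor, n) -> Tensor:
    n = float(n)

    def bw(g):
        self._accumulate(g * n * np.power(self.data, n - 1.0))

    return _from_op(np.power(self.data, n), (self,), bw)


Tensor.__pow__ = _pow


# -- elementwise functions ------------------------------------------------


def exp(x: Tensor) -> Tensor:
    out_data = np.exp(x.data)

    def bw(g):
        x._accumulate(g * out_data)

    return _from_op(out_data, (x,), bw)


def log(x: Tensor) -> Tensor:
    def bw(g):
        x._accumulate(g / x.data)

    return _from_op(np.log(x.data), (x,), bw)


def sqrt(x: Tensor) -> Tensor:
    out_data = np.sqrt(x.data)

    def bw(g):
        x._accumulate(g * 0.5 / out_data)

    return _from_op(out_data, (x,), bw)


def sigmoid(x: Tensor) -> Tensor:
    # clip before exp to avoid overflow warnings in float32
    z = np.clip(x.data, -60.0, 60.0)
    s = 1.0 / (1.0 + np.exp(-z))

    def bw(g):
        x._accumulate(g * s * (1.0 - s))

    return _from_op(s, (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accumulate(g * mask)

    return _from_op(x.data * mask, (x,), bw)


def hardswish(x: Tensor) -> Tensor:
    """x * relu6(x + 3) / 6 — the non-linearity of the coordinate-attention squeeze."""
    d = x.data
    inner = np.clip(d + 3.0, 0.0, 6.0)
    out_data = d * inner / 6.0

    def bw(g):
        grad = np.where(d <= -3.0, 0.0, np.where(d >= 3.0, 1.0, (2.0 * d + 3.0) / 6.0))
        x._accumulate(g * grad.astype(d.dtype))

    return _from_op(out_data, (x,), bw)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with straight-through gradient inside the bounds."""
    mask = (x.data >= lo) & (x.data <= hi)

    def bw(g):
        x._accumulate(g * mask)

    return _from_op(np.clip(x.data, lo, hi), (x,), bw)


# -- reductions / shape ---------------------------------------------------


def _sum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    axes = axis if axis is None or isinstance(axis, tuple) else (axis,)

    def bw(g):
        if axes is None:
            x._accumulate(np.broadcast_to(g, x.data.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axes)
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    return _from_op(x.data.sum(axis=axis, keepdims=keepdims), (x,), bw)


def _mean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return _sum(x, axis=axis, keepdims=keepdims) * (1.0 / n)


Tensor.sum = _sum
Tensor.mean = _mean


def _reshape(x: Tensor, *shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])

    def bw(g):
        x._accumulate(g.reshape(x.data.shape))

    return _from_op(x.data.reshape(shape), (x,), bw)


Tensor.reshape = _reshape


def _getitem(x: Tensor, idx) -> Tensor:
    def bw(g):
        full = np.zeros_like(x.data)
        full[idx] = g
        x._accumulate(full)

    return _from_op(x.data[idx], (x,), bw)


Tensor.__getitem__ = _getitem


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            if t.requires_grad or t._parents:
                t._accumulate(g[tuple(sl)])
            start += s

    return _from_op(data, tuple(tensors), bw)


def bce_with_logits(z: Tensor, y) -> Tensor:
    """Element-wise binary cross-entropy from pre-sigmoid scores.

    Numerically stable form max(z,0) - z*y + log(1 + exp(-|z|)); the gradient
    w.r.t. z is sigmoid(z) - y.
    """
    yd = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=z.data.dtype)
    zd = z.data
    out_data = np.maximum(zd, 0.0) - zd * yd + np.log1p(np.exp(-np.abs(zd)))

    def bw(g):
        s = 1.0 / (1.0 + np.exp(-np.clip(zd, -60.0, 60.0)))
        z._accumulate(g * (s - yd))

    return _from_op(out_data, (z,), bw)
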