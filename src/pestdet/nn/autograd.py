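"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a ``float32`` ndarray and records the operations
applied to it on a tape; :meth:`Tensor.backward` replays the tape in reverse
topological order.  The op set is exactly what a small convolutional detector
and its losses need: broadcasting arithmetic, transcendental elementwise ops,
batched matmul, reductions, shape surgery, and slicing.  Convolutions and the
other structured NN ops live in :mod:`pestdet.nn.functional`.

Gradient semantics follow the usual conventions: ``detach`` cuts the tape,
``no_grad`` disables recording wholesale, and broadcasting backward sums the
upstream gradient over the broadcast axes.
"""
from __future__ import annotations

import contextlib
from typing import Callable, Iterable

import numpy as np
from scipy.special import expit as _expit

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables tape recording."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def is_grad_enabled() -> bool:
    return _grad_enabled


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer mixed ndarray-Tensor arithmetic to our reflected ops
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        else:
            grad = np.asarray(grad, dtype=np.float32)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        # release the tape
        for node in topo:
            if node is not self:
                node._backward = None
                node._parents = ()

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad


def _make(data: np.ndarray, parents: Iterable[Tensor], backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if _grad_enabled and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------- arithmetic
def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def back(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), back)


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data - b.data

    def back(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(-g, b.data.shape))

    return _make(out_data, (a, b), back)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def back(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), back)


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data / b.data

    def back(g):
        a._accum(_unbroadcast(g / b.data, a.data.shape))
        b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out_data, (a, b), back)


def neg(a):
    a = as_tensor(a)
    return _make(-a.data, (a,), lambda g: a._accum(-g))


def pow_(a, p: float):
    a = as_tensor(a)
    out_data = a.data ** p

    def back(g):
        a._accum(g * p * a.data ** (p - 1))

    return _make(out_data, (a,), back)


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def back(g):
        a._accum(g * out_data)

    return _make(out_data, (a,), back)


def log(a):
    a = as_tensor(a)
    out_data = np.log(a.data)

    def back(g):
        a._accum(g / a.data)

    return _make(out_data, (a,), back)


def sqrt(a):
    a = as_tensor(a)
    out_data = np.sqrt(a.data)

    def back(g):
        a._accum(g * 0.5 / np.maximum(out_data, 1e-12))

    return _make(out_data, (a,), back)


def arctan(a):
    a = as_tensor(a)
    out_data = np.arctan(a.data)

    def back(g):
        a._accum(g / (1.0 + a.data * a.data))

    return _make(out_data, (a,), back)


def sigmoid(a):
    a = as_tensor(a)
    out_data = _expit(a.data)

    def back(g):
        a._accum(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), back)


def silu(a):
    """x * sigmoid(x) (the SiLU / swish activation)."""
    a = as_tensor(a)
    s = _expit(a.data)
    out_data = a.data * s

    def back(g):
        a._accum(g * (s * (1.0 + a.data * (1.0 - s))))

    return _make(out_data, (a,), back)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def back(g):
        a._accum(g * mask)

    return _make(out_data, (a,), back)


def maximum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.maximum(a.data, b.data)
    mask = (a.data >= b.data).astype(np.float32)

    def back(g):
        a._accum(_unbroadcast(g * mask, a.data.shape))
        b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return _make(out_data, (a, b), back)


def minimum(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.minimum(a.data, b.data)
    mask = (a.data <= b.data).astype(np.float32)

    def back(g):
        a._accum(_unbroadcast(g * mask, a.data.shape))
        b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

    return _make(out_data, (a, b), back)


def clip(a, lo: float | None, hi: float | None):
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data)
    if lo is not None:
        mask *= a.data >= lo
    if hi is not None:
        mask *= a.data <= hi

    def back(g):
        a._accum(g * mask)

    return _make(out_data, (a,), back)


# ---------------------------------------------------------------- reductions
def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def back(g):
        if axis is None:
            a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))
            return
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g2, a.data.shape).astype(np.float32))

    return _make(out_data, (a,), back)


def mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(sum_(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def softmax(a, axis=-1):
    a = as_tensor(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return _make(out_data, (a,), back)


# ------------------------------------------------------------------- linalg
def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def back(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        a._accum(_unbroadcast(ga, a.data.shape))
        b._accum(_unbroadcast(gb, b.data.shape))

    return _make(out_data, (a, b), back)


# ------------------------------------------------------------- shape surgery
def reshape(a, shape):
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def back(g):
        a._accum(g.reshape(a.data.shape))

    return _make(out_data, (a,), back)


def transpose(a, axes):
    a = as_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def back(g):
        a._accum(np.transpose(g, inv))

    return _make(out_data, (a,), back)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    return _make(out_data, tuple(tensors), back)


def getitem(a, idx):
    a = as_tensor(a)
    out_data = a.data[idx]

    def back(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        a._accum(full)

    return _make(out_data, (a,), back)


def pad2d(a, pad_h: int, pad_w: int):
    """Zero-pad the last two axes symmetrically."""
    a = as_tensor(a)
    if pad_h == 0 and pad_w == 0:
        return a
    widths = [(0, 0)] * (a.data.ndim - 2) + [(pad_h, pad_h), (pad_w, pad_w)]
    out_data = np.pad(a.data, widths)

    def back(g):
        sl = [slice(None)] * (g.ndim - 2) + [
            slice(pad_h, g.shape[-2] - pad_h),
            slice(pad_w, g.shape[-1] - pad_w),
        ]
        a._accum(g[tuple(sl)])

    return _make(out_data, (a,), back)


def broadcast_to(a, shape):
    a = as_tensor(a)
    out_data = np.broadcast_to(a.data, shape).copy()

    def back(g):
        a._accum(_unbroadcast(g, a.data.shape))

    return _make(out_data, (a,), back)


# ------------------------------------------------------------- operator glue
Tensor.__add__ = lambda self, o: add(self, o)
Tensor.__radd__ = lambda self, o: add(o, self)
Tensor.__sub__ = lambda self, o: sub(self, o)
Tensor.__rsub__ = lambda self, o: sub(o, self)
Tensor.__mul__ = lambda self, o: mul(self, o)
Tensor.__rmul__ = lambda self, o: mul(o, self)
Tensor.__truediv__ = lambda self, o: div(self, o)
Tensor.__rtruediv__ = lambda self, o: div(o, self)
Tensor.__neg__ = lambda self: neg(self)
Tensor.__pow__ = lambda self, p: pow_(self, p)
Tensor.__matmul__ = lambda self, o: matmul(self, o)
Tensor.__getitem__ = lambda self, idx: getitem(self, idx)
Tensor.reshape = lambda self, *shape: reshape(
    self, shape[0] if len(shape) == 1 and isinstance(shape[0], (tuple, list)) else shape
)
Tensor.transpose = lambda self, *axes: transpose(
    self, axes[0] if len(axes) == 1 and isinstance(axes[0], (tuple, list)) else axes
)
Tensor.sum = lambda self, axis=None, keepdims=False: sum_(self, axis, keepdims)
Tensor.mean = lambda self, axis=None, keepdims=False: mean(self, axis, keepdims)
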