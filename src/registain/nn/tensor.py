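"""Compact reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations needed by the staining networks and their
losses: elementwise arithmetic, matmul, reductions, slicing, padding,
convolution, pooling, nearest-neighbour upsampling, sliding-window sums and
differentiable bilinear displacement sampling.  Gradients are accumulated by
a topological-order sweep over the recorded graph.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_STACK = [True]


@contextmanager
def no_grad():
    """Disable graph recording inside the context."""
    _GRAD_STACK.append(False)
    try:
        yield
    finally:
        _GRAD_STACK.pop()


def grad_enabled() -> bool:
    return _GRAD_STACK[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        if self.data.dtype.kind not in "fc":
            self.data = self.data.astype(np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = ()
        self._backward = None

    # ------------------------------------------------------------------ infra
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs from training loops can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __rtruediv__(self, other):
        return mul(power(self, -1.0), other)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # ---------------------------------------------------------------- methods
    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if len(axes) > 1 else axes[0])

    def abs(self):
        return tabs(self)

    def exp(self):
        return texp(self)

    def sqrt(self):
        return tsqrt(self)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if grad_enabled() and any(isinstance(p, Tensor) and p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward
    return out


def _acc(t: Tensor, g: np.ndarray) -> None:
    if not (isinstance(t, Tensor) and t.requires_grad):
        return
    if t.grad is None:
        t.grad = np.array(g, dtype=t.data.dtype, copy=True)
    else:
        t.grad += g


# --------------------------------------------------------------------- prims
def add(a, b):
    at, bt = as_tensor(a), as_tensor(b)
    out_data = at.data + bt.data

    def backward(g):
        _acc(at, _unbroadcast(g, at.data.shape))
        _acc(bt, _unbroadcast(g, bt.data.shape))

    return _make(out_data, (at, bt), backward)


def mul(a, b):
    at, bt = as_tensor(a), as_tensor(b)
    out_data = at.data * bt.data

    def backward(g):
        _acc(at, _unbroadcast(g * bt.data, at.data.shape))
        _acc(bt, _unbroadcast(g * at.data, bt.data.shape))

    return _make(out_data, (at, bt), backward)


def power(a, exponent: float):
    at = as_tensor(a)
    out_data = at.data ** exponent

    def backward(g):
        _acc(at, g * exponent * at.data ** (exponent - 1.0))

    return _make(out_data, (at,), backward)


def texp(a):
    at = as_tensor(a)
    out_data = np.exp(at.data)

    def backward(g):
        _acc(at, g * out_data)

    return _make(out_data, (at,), backward)


def tlog(a):
    at = as_tensor(a)

    def backward(g):
        _acc(at, g / at.data)

    return _make(np.log(at.data), (at,), backward)


def tsqrt(a):
    at = as_tensor(a)
    out_data = np.sqrt(at.data)

    def backward(g):
        _acc(at, g * 0.5 / np.maximum(out_data, np.finfo(out_data.dtype).tiny))

    return _make(out_data, (at,), backward)


def tabs(a):
    at = as_tensor(a)
    sign = np.sign(at.data)

    def backward(g):
        _acc(at, g * sign)

    return _make(np.abs(at.data), (at,), backward)


def where(cond, a, b):
    """Select elementwise; ``cond`` is a plain boolean array (not differentiated)."""
    cond = np.asarray(cond)
    at, bt = as_tensor(a), as_tensor(b)
    out_data = np.where(cond, at.data, bt.data)

    def backward(g):
        _acc(at, _unbroadcast(np.where(cond, g, 0.0), at.data.shape))
        _acc(bt, _unbroadcast(np.where(cond, 0.0, g), bt.data.shape))

    return _make(out_data, (at, bt), backward)


def tsum(a, axis=None, keepdims=False):
    at = as_tensor(a)
    out_data = at.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a % at.data.ndim for a in axes):
                g = np.expand_dims(g, ax)
        _acc(at, np.broadcast_to(g, at.data.shape))

    return _make(out_data, (at,), backward)


def tmean(a, axis=None, keepdims=False):
    at = as_tensor(a)
    n = at.data.size if axis is None else np.prod(
        [at.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(at, axis=axis, keepdims=keepdims), 1.0 / float(n))


def matmul(a, b):
    at, bt = as_tensor(a), as_tensor(b)
    out_data = at.data @ bt.data

    def backward(g):
        ga = g @ np.swapaxes(bt.data, -1, -2)
        gb = np.swapaxes(at.data, -1, -2) @ g
        _acc(at, _unbroadcast(ga, at.data.shape))
        _acc(bt, _unbroadcast(gb, bt.data.shape))

    return _make(out_data, (at, bt), backward)


def reshape(a, shape):
    at = as_tensor(a)

    def backward(g):
        _acc(at, g.reshape(at.data.shape))

    return _make(at.data.reshape(shape), (at,), backward)


def transpose(a, axes):
    at = as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        _acc(at, g.transpose(inv))

    return _make(at.data.transpose(axes), (at,), backward)


def getitem(a, idx):
    at = as_tensor(a)

    def backward(g):
        ga = np.zeros_like(at.data)
        ga[idx] += g
        _acc(at, ga)

    return _make(at.data[idx], (at,), backward)


def concatenate(tensors, axis=0):
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(ts, np.split(g, splits, axis=axis)):
            _acc(t, piece)

    return _make(np.concatenate([t.data for t in ts], axis=axis), tuple(ts), backward)


# --------------------------------------------------- activations (primitives)
def relu(a):
    at = as_tensor(a)
    mask = at.data > 0

    def backward(g):
        _acc(at, g * mask)

    return _make(at.data * mask, (at,), backward)


def leaky_relu(a, alpha: float = 0.1):
    at = as_tensor(a)
    mask = at.data > 0
    out_data = np.where(mask, at.data, alpha * at.data)

    def backward(g):
        _acc(at, np.where(mask, g, alpha * g))

    return _make(out_data, (at,), backward)


def sigmoid(a):
    at = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-np.clip(at.data, -60.0, 60.0)))

    def backward(g):
        _acc(at, g * out_data * (1.0 - out_data))

    return _make(out_data, (at,), backward)


def tanh(a):
    at = as_tensor(a)
    out_data = np.tanh(at.data)

    def backward(g):
        _acc(at, g * (1.0 - out_data ** 2))

    return _make(out_data, (at,), backward)
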