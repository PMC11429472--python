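"""Compact reverse-mode automatic differentiation over NumPy arrays.

The whole network stack in this package (encoder branches, fusion gates,
decoder, prompt controller, losses) is expressed as compositions of the
primitives defined here.  Each primitive records its parents and a closure
that maps the output cotangent onto the parents; :meth:`Tensor.backward`
replays those closures in reverse topological order.

Design constraints:

* arrays are ``float32`` by default (``float64`` is allowed and preserved,
  which the finite-difference gradient checks rely on);
* broadcasting follows NumPy semantics — cotangents are summed back down to
  the parent shape;
* graph recording can be suspended wholesale with :func:`no_grad`, which
  inference paths use to keep memory flat.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np
from scipy.special import erf as _erf, expit as _expit

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "is_grad_enabled",
    "concatenate",
    "maximum",
    "where_mask",
]

_GRAD_ENABLED = True

_SQRT_2 = math.sqrt(2.0)
_INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)


@contextmanager
def no_grad():
    """Suspend graph recording inside the ``with`` block."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _coerce(data) -> np.ndarray:
    arr = np.asarray(data)
    if arr.dtype not in (np.float32, np.float64):
        arr = arr.astype(np.float32)
    return arr


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional autodiff tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _coerce(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- bookkeeping ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Backpropagate from this tensor (must be scalar if ``grad`` is None)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit cotangent needs a scalar")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        if not np.isscalar(exponent):
            raise TypeError("only scalar exponents are supported")
        out_data = self.data ** exponent

        def bwd(g, a=self, e=exponent, od=out_data):
            a._accumulate(g * e * a.data ** (e - 1.0))

        return Tensor._make(out_data, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
                a._accumulate(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(np.matmul(self.data, other.data), (self, other), bwd)

    # -- pointwise nonlinearities --------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, od=out_data):
            a._accumulate(g * od)

        return Tensor._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bwd(g, a=self, od=out_data):
            a._accumulate(g * 0.5 / od)

        return Tensor._make(out_data, (self,), bwd)

    def sigmoid(self):
        out_data = _expit(self.data)  # numerically stable for large |x|

        def bwd(g, a=self, od=out_data):
            a._accumulate(g * od * (1.0 - od))

        return Tensor._make(out_data, (self,), bwd)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bwd(g, a=self, od=out_data):
            a._accumulate(g * (1.0 - od * od))

        return Tensor._make(out_data, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self, m=mask):
            a._accumulate(g * m)

        return Tensor._make(self.data * mask, (self,), bwd)

    def gelu(self):
        # exact (erf) form; derivative Phi(x) + x * phi(x)
        x = self.data
        phi_cdf = 0.5 * (1.0 + _erf(x / _SQRT_2))
        out_data = x * phi_cdf

        def bwd(g, a=self, cdf=phi_cdf):
            xx = a.data
            pdf = _INV_SQRT_2PI * np.exp(-0.5 * xx * xx)
            a._accumulate(g * (cdf + xx * pdf))

        return Tensor._make(out_data, (self,), bwd)

    # -- reductions -----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g, a=self, ax=axis, kd=keepdims):
            if ax is None:
                ga = np.broadcast_to(g, a.shape)
            else:
                gg = g if kd else np.expand_dims(g, ax)
                ga = np.broadcast_to(gg, a.shape)
            a._accumulate(ga.astype(a.data.dtype))

        return Tensor._make(out_data, (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ---------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old_shape = self.data.shape

        def bwd(g, a=self, s=old_shape):
            a._accumulate(g.reshape(s))

        return Tensor._make(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(g, a=self, iv=inv):
            a._accumulate(g.transpose(iv))

        return Tensor._make(self.data.transpose(axes), (self,), bwd)

    def __getitem__(self, idx):
        advanced = isinstance(idx, np.ndarray) or (
            isinstance(idx, tuple) and any(isinstance(i, (np.ndarray, list)) for i in idx)
        )
        out_data = self.data[idx]

        def bwd(g, a=self, ix=idx, adv=advanced):
            ga = np.zeros_like(a.data)
            if adv:
                np.add.at(ga, ix, g)
            else:
                ga[ix] += g
            a._accumulate(ga)

        return Tensor._make(out_data, (self,), bwd)

    def pad(self, pad_width):
        """Zero padding; ``pad_width`` as for :func:`numpy.pad`."""
        pw = tuple(tuple(p) for p in pad_width)

        def bwd(g, a=self, p=pw):
            sl = tuple(slice(lo, g.shape[i] - hi if hi else None) for i, (lo, hi) in enumerate(p))
            a._accumulate(g[sl])

        return Tensor._make(np.pad(self.data, pw), (self,), bwd)

    def roll(self, shift, axis):
        def bwd(g, a=self, s=shift, ax=axis):
            a._accumulate(np.roll(g, tuple(-x for x in s) if isinstance(s, tuple) else -s, ax))

        return Tensor._make(np.roll(self.data, shift, axis), (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g, ts=tensors, offs=offsets, ax=axis):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd)


def maximum(a, b) -> Tensor:
    """Elementwise maximum; on ties the cotangent goes to the first argument."""
    a, b = as_tensor(a), as_tensor(b)
    take_a = a.data >= b.data

    def bwd(g, x=a, y=b, m=take_a):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g * m, x.shape))
        if y.requires_grad:
            y._accumulate(_unbroadcast(g * (~m), y.shape))

    return Tensor._make(np.maximum(a.data, b.data), (a, b), bwd)


def where_mask(mask: np.ndarray, a, b) -> Tensor:
    """``mask`` is a constant boolean array; gradients flow to both branches."""
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g, x=a, y=b, m=mask):
        if x.requires_grad:
            x._accumulate(_unbroadcast(g * m, x.shape))
        if y.requires_grad:
            y._accumulate(_unbroadcast(g * (~m), y.shape))

    return Tensor._make(np.where(mask, a.data, b.data), (a, b), bwd)
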