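"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps a float64
``ndarray``; every operation returns a new ``Tensor`` carrying a closure
that routes the upstream gradient to its parents.  ``backward()`` runs the
closures in reverse topological order.  The op set covers exactly what the
model needs — affine layers, elementwise nonlinearities, reductions,
concatenation, fancy row indexing, and ``gammaln`` (whose derivative is the
digamma function, needed by the negative-binomial likelihood).

Everything is float64 and single-threaded numpy, so results are
bit-reproducible across runs on the same platform.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy.special import digamma as _digamma
from scipy.special import expit as _expit
from scipy.special import gammaln as _gammaln

__all__ = [
    "Tensor",
    "concat",
    "exp",
    "log",
    "log1p",
    "relu",
    "softplus",
    "sqrt",
    "clip",
    "gammaln",
    "logsumexp",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast up from `shape`."""
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
    """A float64 array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph plumbing ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        self.grad = g if self.grad is None else self.grad + g

    def backward(self) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = _node(self.data + other.data, (self, other))
        if out.requires_grad:
            def bwd():
                if self.requires_grad:
                    self._accum(out.grad)
                if other.requires_grad:
                    other._accum(out.grad)
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = _node(-self.data, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(-out.grad)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data * other.data, (self, other))
        if out.requires_grad:
            def bwd():
                if self.requires_grad:
                    self._accum(out.grad * other.data)
                if other.requires_grad:
                    other._accum(out.grad * self.data)
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out = _node(self.data / other.data, (self, other))
        if out.requires_grad:
            def bwd():
                if self.requires_grad:
                    self._accum(out.grad / other.data)
                if other.requires_grad:
                    other._accum(-out.grad * self.data / other.data**2)
            out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return _as_tensor(other) / self

    def __pow__(self, p: float):
        out = _node(self.data**p, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad * p * self.data ** (p - 1))
        return out

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = _node(self.data @ other.data, (self, other))
        if out.requires_grad:
            def bwd():
                if self.requires_grad:
                    self._accum(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ out.grad)
            out._backward = bwd
        return out

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            def bwd():
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
            out._backward = bwd
        return out

    # -- reductions / reshaping ------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = _node(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            def bwd():
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape))
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = _node(self.data.T, (self,))
        if out.requires_grad:
            out._backward = lambda: self._accum(out.grad.T)
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    rg = any(p.requires_grad for p in parents)
    out = Tensor(data, rg)
    if rg:
        out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
    return out


# -- elementwise functions -----------------------------------------------


def exp(t: Tensor) -> Tensor:
    out = _node(np.exp(t.data), (t,))
    if out.requires_grad:
        out._backward = lambda: t._accum(out.grad * out.data)
    return out


def log(t: Tensor) -> Tensor:
    out = _node(np.log(t.data), (t,))
    if out.requires_grad:
        out._backward = lambda: t._accum(out.grad / t.data)
    return out


def log1p(t: Tensor) -> Tensor:
    out = _node(np.log1p(t.data), (t,))
    if out.requires_grad:
        out._backward = lambda: t._accum(out.grad / (1.0 + t.data))
    return out


def sqrt(t: Tensor) -> Tensor:
    out = _node(np.sqrt(t.data), (t,))
    if out.requires_grad:
        # subgradient 0 at exactly 0 keeps group-lasso columns at the origin stable
        def bwd():
            d = np.where(out.data > 0, 2.0 * out.data, np.inf)
            t._accum(out.grad / d)
        out._backward = bwd
    return out


def relu(t: Tensor) -> Tensor:
    out = _node(np.maximum(t.data, 0.0), (t,))
    if out.requires_grad:
        out._backward = lambda: t._accum(out.grad * (t.data > 0))
    return out


def softplus(t: Tensor) -> Tensor:
    out = _node(np.logaddexp(0.0, t.data), (t,))
    if out.requires_grad:
        out._backward = lambda: t._accum(out.grad * _expit(t.data))
    return out


def clip(t: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with zero gradient outside [lo, hi]."""
    out = _node(np.clip(t.data, lo, hi), (t,))
    if out.requires_grad:
        mask = (t.data >= lo) & (t.data <= hi)
        out._backward = lambda: t._accum(out.grad * mask)
    return out


def gammaln(t: Tensor) -> Tensor:
    out = _node(_gammaln(t.data), (t,))
    if out.requires_grad:
        out._backward = lambda: t._accum(out.grad * _digamma(t.data))
    return out


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        def bwd():
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                if t.requires_grad or t._parents:
                    t._accum(g)
        out._backward = bwd
    return out


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    m = np.max(t.data, axis=axis, keepdims=True)
    s = log(exp(t - Tensor(m)).sum(axis=axis, keepdims=True)) + Tensor(m)
    return s if keepdims else s.reshape(np.squeeze(s.data, axis=axis).shape)


# -- optimizer ------------------------------------------------------------


class Adam:
    """Adaptive-moment SGD over a fixed set of named parameters.

    One instance per parameter partition, so moment statistics never mix
    across the alternating update scheme.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = dict(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
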