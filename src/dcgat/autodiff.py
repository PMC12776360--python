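"""Minimal reverse-mode tensor autodiff on numpy.

The model needs gradients through graph convolutions, masked attention
softmaxes and the straight-through Gumbel-softmax estimator.  This module
provides a small dynamically-built tape: a :class:`Tensor` wraps an ndarray,
records its parents and a backward closure, and ``backward()`` walks the
graph in reverse topological order accumulating gradients.

Only the operations the model uses are implemented.  Broadcasting is
supported for elementwise ops; ``matmul`` supports the 2-D and batched
(ND @ 2-D) cases that appear in the network.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100  # so ndarray + Tensor defers to us

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return self._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return self._make(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return self._make(self.data ** p, (self,), bwd)

    def matmul(self, other):
        other = self._wrap(other)
        a_nd, b_nd = self.data.ndim, other.data.ndim

        def bwd(g, a=self, b=other):
            if a.requires_grad:
                if b_nd == 2:
                    a._accum(g @ b.data.T)
                else:
                    a._accum(np.matmul(g, np.swapaxes(b.data, -1, -2)))
            if b.requires_grad:
                if b_nd == 2 and a_nd > 2:
                    # batched A (.., k) @ B (k, n): sum over batch dims
                    k = a.data.shape[-1]
                    n = g.shape[-1]
                    b._accum(a.data.reshape(-1, k).T @ g.reshape(-1, n))
                else:
                    b._accum(
                        _unbroadcast(
                            np.matmul(np.swapaxes(a.data, -1, -2), g), b.shape
                        )
                    )

        return self._make(np.matmul(self.data, other.data), (self, other), bwd)

    __matmul__ = matmul

    @property
    def T(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g.T)

        return self._make(self.data.T, (self,), bwd)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, od=out_data):
            if a.requires_grad:
                a._accum(g * od)

        return self._make(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return self._make(np.log(self.data), (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1.0 - s))

        return self._make(s, (self,), bwd)

    def tanh(self):
        t = np.tanh(self.data)

        def bwd(g, a=self, t=t):
            if a.requires_grad:
                a._accum(g * (1.0 - t * t))

        return self._make(t, (self,), bwd)

    def relu(self):
        mask = self.data > 0

        def bwd(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)

        return self._make(self.data * mask, (self,), bwd)

    def leaky_relu(self, slope: float = 0.2):
        mask = self.data > 0
        factor = np.where(mask, 1.0, slope)

        def bwd(g, a=self, factor=factor):
            if a.requires_grad:
                a._accum(g * factor)

        return self._make(self.data * factor, (self,), bwd)

    def elu(self, alpha: float = 1.0):
        mask = self.data > 0
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(mask, self.data, neg)

        def bwd(g, a=self, mask=mask, neg=neg):
            if a.requires_grad:
                a._accum(g * np.where(mask, 1.0, neg + alpha))

        return self._make(out_data, (self,), bwd)

    def clip(self, lo: float, hi: float):
        mask = (self.data > lo) & (self.data < hi)

        def bwd(g, a=self, mask=mask):
            if a.requires_grad:
                a._accum(g * mask)

        return self._make(np.clip(self.data, lo, hi), (self,), bwd)

    # -- reductions / reshaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a=self):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.shape

        def bwd(g, a=self, orig=orig):
            if a.requires_grad:
                a._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def take(self, indices, axis: int = 0):
        """Row gather (with repetition) along `axis`; gradients scatter-add."""
        indices = np.asarray(indices)

        def bwd(g, a=self, idx=indices):
            if a.requires_grad:
                acc = np.zeros_like(a.data)
                np.add.at(acc, idx if axis == 0 else (slice(None), idx), g)
                a._accum(acc)

        return self._make(np.take(self.data, indices, axis=axis), (self,), bwd)

    # -- tape mechanics -------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def constant(data) -> Tensor:
    """A tensor outside the tape (gradients never flow into it)."""
    return Tensor(data, requires_grad=False)


def concat(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), bwd)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
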