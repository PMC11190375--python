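"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the survival network needs: (batched) matrix
products, broadcast add/multiply, elementwise nonlinearities, softmax, log/exp,
axis reductions, concatenation and row gathering.  Gradients are accumulated by
a topological-order backward sweep.  Correctness is pinned by finite-difference
tests on the full Cox training objective.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (undo numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum extra leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("value", "grad", "requires_grad", "_parents")

    def __init__(self, value, parents=(), requires_grad=False):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        # parents: tuple of (Tensor, fn: upstream_grad -> grad wrt parent)
        self._parents = tuple(parents)

    @property
    def shape(self):
        return self.value.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        return Tensor(
            self.value + other.value,
            parents=((self, lambda g: _unbroadcast(g, self.shape)),
                     (other, lambda g: _unbroadcast(g, other.shape))),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.value, parents=((self, lambda g: -g),))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        a, b = self.value, other.value
        return Tensor(
            a * b,
            parents=((self, lambda g: _unbroadcast(g * b, self.shape)),
                     (other, lambda g: _unbroadcast(g * a, other.shape))),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        a, b = self.value, other.value
        return Tensor(
            a / b,
            parents=((self, lambda g: _unbroadcast(g / b, self.shape)),
                     (other, lambda g: _unbroadcast(-g * a / (b * b), other.shape))),
        )

    def matmul(self, other):
        """Matrix product; supports batched left operand against a 2-D right."""
        other = self._lift(other)
        a, b = self.value, other.value

        def swap(x):
            return np.swapaxes(x, -1, -2)

        return Tensor(
            a @ b,
            parents=((self, lambda g: _unbroadcast(g @ swap(b), self.shape)),
                     (other, lambda g: _unbroadcast(swap(a) @ g, other.shape))),
        )

    __matmul__ = matmul

    # ---- nonlinearities ---------------------------------------------------

    def relu(self):
        mask = (self.value > 0).astype(np.float64)
        return Tensor(self.value * mask, parents=((self, lambda g: g * mask),))

    def tanh(self):
        out = np.tanh(self.value)
        return Tensor(out, parents=((self, lambda g: g * (1.0 - out * out)),))

    def sigmoid(self):
        out = 0.5 * (1.0 + np.tanh(0.5 * self.value))
        return Tensor(out, parents=((self, lambda g: g * out * (1.0 - out)),))

    def softplus(self):
        # stable: log(1 + e^x) = max(x,0) + log1p(e^{-|x|})
        x = self.value
        out = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
        sig = 0.5 * (1.0 + np.tanh(0.5 * x))
        return Tensor(out, parents=((self, lambda g: g * sig),))

    def exp(self):
        out = np.exp(self.value)
        return Tensor(out, parents=((self, lambda g: g * out),))

    def log(self):
        return Tensor(np.log(self.value),
                      parents=((self, lambda g: g / self.value),))

    def softmax(self, axis=-1):
        x = self.value
        s = np.exp(x - x.max(axis=axis, keepdims=True))
        s /= s.sum(axis=axis, keepdims=True)

        def back(g, s=s, axis=axis):
            return s * (g - (g * s).sum(axis=axis, keepdims=True))

        return Tensor(s, parents=((self, back),))

    # ---- shape ops ---------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.value.sum(axis=axis, keepdims=keepdims)

        def back(g, shape=self.shape, axis=axis, keepdims=keepdims):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape).copy()

        return Tensor(out, parents=((self, back),))

    def mean(self, axis=None, keepdims=False):
        n = self.value.size if axis is None else self.value.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def take_rows(self, idx):
        idx = np.asarray(idx, dtype=np.intp)
        out = self.value[idx]

        def back(g, shape=self.shape, idx=idx):
            full = np.zeros(shape, dtype=np.float64)
            np.add.at(full, idx, g)
            return full

        return Tensor(out, parents=((self, back),))

    def slice_cols(self, start, stop):
        out = self.value[..., start:stop]

        def back(g, shape=self.shape, start=start, stop=stop):
            full = np.zeros(shape, dtype=np.float64)
            full[..., start:stop] = g
            return full

        return Tensor(out, parents=((self, back),))

    def reshape(self, *shape):
        old = self.shape
        return Tensor(self.value.reshape(*shape),
                      parents=((self, lambda g: g.reshape(old)),))

    @staticmethod
    def concat(tensors, axis=0):
        tensors = [Tensor._lift(t) for t in tensors]
        out = np.concatenate([t.value for t in tensors], axis=axis)
        sizes = [t.value.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        parents = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            def back(g, lo=int(lo), hi=int(hi), axis=axis):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                return g[tuple(sl)]
            parents.append((t, back))
        return Tensor(out, parents=tuple(parents))

    # ---- backward ----------------------------------------------------------

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.value)
        # topological order over the subgraph reachable from self
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p, _ in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad:
                t.grad = g if t.grad is None else t.grad + g
            for p, fn in t._parents:
                pg = fn(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)
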