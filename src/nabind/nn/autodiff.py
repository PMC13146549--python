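"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the tensor operations the fusion network needs: broadcasted
arithmetic, batched matmul, relu, softmax/log-softmax, reductions, reshape /
transpose / concatenate, and elementwise transcendentals.  Gradients are
accumulated in float64.  The graph is built eagerly; ``Tensor.backward()``
runs a topological sweep.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        # parents: tuple of (Tensor, vjp) where vjp maps upstream grad -> parent grad
        self._parents = parents

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- graph construction ------------------------------------------------

    @staticmethod
    def _make(data, parents):
        parents = tuple((p, vjp) for p, vjp in parents if p.requires_grad)
        return Tensor(data, requires_grad=bool(parents), parents=parents)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            stack = [(node, False)]
            while stack:
                n, processed = stack.pop()
                if processed:
                    topo.append(n)
                    continue
                if id(n) in seen:
                    continue
                seen.add(id(n))
                stack.append((n, True))
                for p, _ in n._parents:
                    stack.append((p, False))

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and not node._parents:  # leaf
                node.grad = g if node.grad is None else node.grad + g
            for p, vjp in node._parents:
                pg = vjp(g)
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                elif p._parents:
                    grads[id(p)] = pg
                else:
                    p.grad = pg if p.grad is None else p.grad + pg

    # -- operators ---------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = self.data + other.data
        return Tensor._make(
            out,
            [
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ],
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, [(self, lambda g: -g)])

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data * other.data,
            [
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ],
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._make(
            self.data / other.data,
            [
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(-g * self.data / other.data**2, other.data.shape),
                ),
            ],
        )

    def __matmul__(self, other):
        other = as_tensor(other)
        out = self.data @ other.data

        def grad_a(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            return _unbroadcast(ga, self.data.shape)

        def grad_b(g):
            gb = np.swapaxes(self.data, -1, -2) @ g
            return _unbroadcast(gb, other.data.shape)

        return Tensor._make(out, [(self, grad_a), (other, grad_b)])

    def __getitem__(self, key):
        out = self.data[key]

        def vjp(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return full

        return Tensor._make(out, [(self, vjp)])

    # -- elementwise -------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        return Tensor._make(self.data * mask, [(self, lambda g: g * mask)])

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, [(self, lambda g: g * out)])

    def log(self):
        return Tensor._make(np.log(self.data), [(self, lambda g: g / self.data)])

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, [(self, lambda g: g / (2.0 * out))])

    def pow(self, exponent: float):
        out = self.data**exponent
        return Tensor._make(
            out, [(self, lambda g: g * exponent * self.data ** (exponent - 1))]
        )

    # -- reductions / shape ------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            g2 = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(g2, self.data.shape).copy()

        return Tensor._make(out, [(self, vjp)])

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            n = self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        return Tensor._make(
            self.data.reshape(*shape), [(self, lambda g: g.reshape(old))]
        )

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return Tensor._make(
            self.data.transpose(axes), [(self, lambda g: g.transpose(inv))]
        )

    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        out = e / e.sum(axis=axis, keepdims=True)

        def vjp(g):
            return out * (g - (g * out).sum(axis=axis, keepdims=True))

        return Tensor._make(out, [(self, vjp)])

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        soft = np.exp(out)

        def vjp(g):
            return g - soft * g.sum(axis=axis, keepdims=True)

        return Tensor._make(out, [(self, vjp)])


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concatenate(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def make_vjp(i):
        def vjp(g):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(offsets[i], offsets[i + 1])
            return g[tuple(sl)]

        return vjp

    return Tensor._make(out, [(t, make_vjp(i)) for i, t in enumerate(tensors)])
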