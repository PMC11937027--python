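"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Just enough machinery for the variational graph encoder and its losses:
dense tensors, a dynamically built tape, and the dozen primitives the
forward pass uses.  Gradients support NumPy broadcasting (the adjoint is
summed over broadcast axes).  Correctness is pinned down by
finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "relu", "sigmoid", "exp", "log", "sqrt", "matmul", "tsum"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum an adjoint down to ``shape`` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node of the computation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None

    # -- construction -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _make(cls, data, parents, backward) -> "Tensor":
        out = cls(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ---------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        def backward(g):
            return _unbroadcast(g, self.shape), _unbroadcast(g, other.shape)
        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )
        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )
        return self._make(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        def backward(g):
            return g @ other.data.T, self.data.T @ g
        return self._make(self.data @ other.data, (self, other), backward)

    @property
    def T(self) -> "Tensor":
        return self._make(self.data.T, (self,), lambda g: (g.T,))

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff -----------------------------------------------------
    def backward(self):
        """Accumulate d(self)/d(leaf) into every reachable leaf's .grad."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen or not node.requires_grad:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        grads = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:  # leaf
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            # leaves inside _parents with no _backward are handled on pop
        # flush grads for leaves that were parents but never visited as nodes
        for node in topo:
            if node._backward is None and id(node) in grads:
                node.grad = grads.pop(id(node))

    def zero_grad(self):
        self.grad = None


def constant(x) -> Tensor:
    return Tensor(x, requires_grad=False)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor._make(np.where(mask, x.data, 0.0), (x,), lambda g: (g * mask,))


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor._make(s, (x,), lambda g: (g * s * (1 - s),))


def exp(x: Tensor) -> Tensor:
    e = np.exp(x.data)
    return Tensor._make(e, (x,), lambda g: (g * e,))


def log(x: Tensor) -> Tensor:
    return Tensor._make(np.log(x.data), (x,), lambda g: (g / x.data,))


def sqrt(x: Tensor) -> Tensor:
    r = np.sqrt(x.data)
    return Tensor._make(r, (x,), lambda g: (g * 0.5 / r,))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    return a @ b


def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    return x.sum(axis=axis, keepdims=keepdims)
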