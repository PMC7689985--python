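"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the encoder/decoder stack needs: dense and
sparse-times-dense matrix products, broadcasting elementwise arithmetic,
row gathering, ReLU/sigmoid, and reductions.  Gradients are accumulated by
topologically-ordered backward passes from a scalar loss.  The engine is
deliberately small; correctness is enforced by finite-difference checks in
the test suite rather than by feature breadth.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = ["Tensor", "spmm", "relu", "sigmoid", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims that were added
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over dims that were size-1 in the original
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _node(data, parents: Sequence["Tensor"]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor._node(self.data + other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        return self * -1.0

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor._node(self.data * other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._lift(other)
        out = Tensor._node(self.data @ other.data, (self, other))

        def backward():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = backward
        return out

    # -- shape / selection ----------------------------------------------------

    def gather_rows(self, idx: np.ndarray) -> "Tensor":
        idx = np.asarray(idx, dtype=np.intp)
        out = Tensor._node(self.data[idx], (self,))

        def backward():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        out._backward = backward
        return out

    def sum(self, axis: int | None = None) -> "Tensor":
        out = Tensor._node(self.data.sum(axis=axis), (self,))

        def backward():
            if self.requires_grad:
                g = out.grad
                if axis is not None:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = backward
        return out

    # -- autodiff driver ------------------------------------------------------

    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                if node.grad is None:
                    node.grad = np.zeros_like(node.data)
                node._backward()


def spmm(A: sp.spmatrix, x: Tensor) -> Tensor:
    """Product of a constant sparse matrix with a differentiable dense matrix."""
    A = sp.csr_matrix(A)
    out = Tensor._node(A @ x.data, (x,))

    def backward():
        if x.requires_grad:
            x._accum(A.T @ out.grad)

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor._node(np.maximum(x.data, 0.0), (x,))

    def backward():
        if x.requires_grad:
            x._accum(out.grad * (x.data > 0))

    out._backward = backward
    return out


def sigmoid(x: Tensor) -> Tensor:
    # numerically stable in both tails
    d = x.data
    val = np.empty_like(d)
    pos = d >= 0
    val[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
    e = np.exp(d[~pos])
    val[~pos] = e / (1.0 + e)
    out = Tensor._node(val, (x,))

    def backward():
        if x.requires_grad:
            x._accum(out.grad * val * (1.0 - val))

    out._backward = backward
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...] | None = None) -> np.ndarray:
    """Glorot/Xavier uniform init: U(-limit, limit), limit = sqrt(6/(fi+fo))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam optimizer over a fixed, ordered parameter list."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
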