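"""Minimal reverse-mode automatic differentiation over numpy arrays.

The classification networks used here are small (two hypergraph
convolutions plus a fully connected head, full batch, a few hundred
samples), so a compact tape-based engine over float64 ndarrays is all
that is needed.  It supports exactly the operations the evidential
losses require — broadcasting arithmetic, matmul, reductions, LeakyReLU,
softplus, and the log-gamma/digamma pair whose derivatives the
Dirichlet losses need — plus an Adam optimizer.

Gradients are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy import special

__all__ = ["Tensor", "Adam", "log", "exp", "softplus", "leaky_relu",
           "lgamma", "digamma"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over the axes that broadcasting expanded to reach `shape`."""
    grad = np.asarray(grad)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._vjp: Callable[[np.ndarray], tuple] | None = None

    # ---- construction helpers -------------------------------------------

    @staticmethod
    def _from_op(data, parents: tuple["Tensor", ...], vjp) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._vjp = vjp
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    # ---- arithmetic ------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        return Tensor._from_op(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __sub__(self, other):
        other = as_tensor(other)
        return Tensor._from_op(
            self.data - other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape), _unbroadcast(-g, other.shape)))

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        other = as_tensor(other)
        return Tensor._from_op(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.shape),
                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return Tensor._from_op(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.shape),
                       _unbroadcast(-g * self.data / other.data ** 2, other.shape)))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __matmul__(self, other):
        other = as_tensor(other)
        return Tensor._from_op(
            self.data @ other.data, (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g))

    # ---- reductions / reshaping -----------------------------------------

    def sum(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape),)

        return Tensor._from_op(data, (self,), vjp)

    def mean(self, axis: int | None = None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape) -> "Tensor":
        return Tensor._from_op(
            self.data.reshape(*shape), (self,),
            lambda g: (g.reshape(self.data.shape),))

    # ---- backward pass ---------------------------------------------------

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                if parent.requires_grad:
                    stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---- elementwise functions ---------------------------------------------


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._from_op(np.log(x.data), (x,), lambda g: (g / x.data,))


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = np.exp(x.data)
    return Tensor._from_op(out, (x,), lambda g: (g * out,))


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), computed stably; derivative is the logistic sigmoid."""
    x = as_tensor(x)
    return Tensor._from_op(
        np.logaddexp(0.0, x.data), (x,),
        lambda g: (g * special.expit(x.data),))


def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    x = as_tensor(x)
    factor = np.where(x.data > 0, 1.0, negative_slope)
    return Tensor._from_op(x.data * factor, (x,), lambda g: (g * factor,))


def lgamma(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._from_op(
        special.gammaln(x.data), (x,),
        lambda g: (g * special.digamma(x.data),))


def digamma(x: Tensor) -> Tensor:
    x = as_tensor(x)
    return Tensor._from_op(
        special.digamma(x.data), (x,),
        lambda g: (g * special.polygamma(1, x.data),))


# ---- optimizer -----------------------------------------------------------


class Adam:
    """Adam with (coupled) L2 weight decay, matching the common default
    of adding ``weight_decay * param`` to the raw gradient."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = b1 * self._m[i] + (1 - b1) * g
            self._v[i] = b2 * self._v[i] + (1 - b2) * g * g
            m_hat = self._m[i] / (1 - b1 ** self._t)
            v_hat = self._v[i] / (1 - b2 ** self._t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
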