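"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the compact regressors in :mod:`anihrv.models`:
broadcast-aware elementwise arithmetic, matrix product, sigmoid/tanh,
axis reductions, reshape/slice/concat, and Adam/Adamax optimizers.
Gradients are validated against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "sigmoid", "tanh", "concat", "Adam", "Adamax"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """Array node in the autodiff graph."""

    __array_priority__ = 1000
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g, out):
            return (_unbroadcast(g * other.data, self.shape), _unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other) ** -1.0

    def __rtruediv__(self, other):
        return self._wrap(other) * self**-1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bw(g, out):
            return (_unbroadcast(g * e * self.data ** (e - 1.0), self.shape),)

        return self._make(self.data**e, (self,), bw)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)

    # -- shaping -------------------------------------------------------
    def reshape(self, *shape):
        def bw(g, out):
            return (g.reshape(self.shape),)

        return self._make(self.data.reshape(*shape), (self,), bw)

    def __getitem__(self, key):
        def bw(g, out):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)

        return self._make(self.data[key], (self,), bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod([self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def abs(self):
        def bw(g, out):
            return (g * np.sign(self.data),)

        return self._make(np.abs(self.data), (self,), bw)

    # -- backward pass -------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(node: "Tensor"):
            stack = [(node, iter(node._parents))]
            if id(node) in seen:
                return
            seen.add(id(node))
            while stack:
                cur, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(cur)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                parent.grad = g if parent.grad is None else parent.grad + g


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g, out):
        return (g * s * (1.0 - s),)

    return Tensor._make(s, (x,), bw)


def tanh(x: Tensor) -> Tensor:
    th = np.tanh(x.data)

    def bw(g, out):
        return (g * (1.0 - th**2),)

    return Tensor._make(th, (x,), bw)


def concat(tensors: list, axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g, out):
        return tuple(
            g[tuple(slice(offsets[i], offsets[i + 1]) if ax == axis else slice(None) for ax in range(g.ndim))]
            for i in range(len(tensors))
        )

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bw)


class _OptimizerBase:
    def __init__(self, params: list, lr: float):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam(_OptimizerBase):
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            m_hat = self.m[i] / (1 - b1**self.t)
            v_hat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class Adamax(_OptimizerBase):
    """Adamax: Adam's infinity-norm variant (second moment -> running max)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        super().__init__(params, lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.u = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1 = self.beta1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.u[i] = np.maximum(self.beta2 * self.u[i], np.abs(g))
            p.data -= (self.lr / (1 - b1**self.t)) * self.m[i] / (self.u[i] + self.eps)
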