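"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical backbone of the perturbation model: a tape-based
scalar-output autodiff with exactly the operations the network needs
(dense matmul, broadcasting arithmetic, ReLU, exp, magnitude powers,
reductions, slicing and row-gather). Gradients are accumulated by a
single reverse topological sweep from a scalar loss.

Design constraints:
  * arrays are float64 throughout — reproducibility and gradient checks
    beat speed at desk scale;
  * ``sign`` is exposed as a constant (zero-gradient) op, matching its
    almost-everywhere derivative; the direction-aware loss is therefore
    a value-only regularizer, as in the sign-based formulation it
    implements;
  * ``abs_power(x, p)`` computes |x|**p with gradient
    p·|x|**(p−1)·sign(x), the convention used by the autofocus loss for
    non-integer exponents.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "relu", "exp", "abs_power", "sign", "concat"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")
    __array_priority__ = 100.0  # so np.ndarray + Tensor defers to us

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
    def _node(data, parents, backward) -> "Tensor":
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

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, out):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def backward(g, out):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division only supported by constants")
        return self * (1.0 / other)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self.data, other.data

        def backward(g, out):
            if self.requires_grad:
                self._accum(g @ b.T)
            if other.requires_grad:
                other._accum(a.T @ g)

        return Tensor._node(a @ b, (self, other), backward)

    # -- shaping --------------------------------------------------------------
    def transpose(self):
        if self.data.ndim != 2:
            raise ValueError("transpose supports 2-D tensors only")

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.T)

        return Tensor._node(self.data.T, (self,), backward)

    def reshape(self, *shape):
        old = self.data.shape

        def backward(g, out):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._node(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, idx):
        def backward(g, out):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return Tensor._node(self.data[idx], (self,), backward)

    def gather_rows(self, index: np.ndarray):
        """Row lookup ``self[index]`` with scatter-add gradient (embedding lookup)."""
        index = np.asarray(index, dtype=np.intp)

        def backward(g, out):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, index, g)
                self._accum(full)

        return Tensor._node(self.data[index], (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, out):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).copy())

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            # grad can stay None below zero-gradient ops (e.g. sign)
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad, t)

    def item(self) -> float:
        return float(self.data)


# -- elementwise nonlinearities ----------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._node(np.where(mask, x.data, 0.0), (x,), backward)


def exp(x: Tensor) -> Tensor:
    val = np.exp(x.data)

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * val)

    return Tensor._node(val, (x,), backward)


def abs_power(x: Tensor, p: float) -> Tensor:
    """|x|**p with derivative p·|x|**(p−1)·sign(x); p >= 1."""
    ax = np.abs(x.data)

    def backward(g, out):
        if x.requires_grad:
            x._accum(g * p * ax ** (p - 1.0) * np.sign(x.data))

    return Tensor._node(ax**p, (x,), backward)


def sign(x: Tensor) -> Tensor:
    """sign(x) as a constant (zero-gradient almost everywhere)."""
    return Tensor._node(np.sign(x.data), (x,), lambda g, out: None)


def concat(tensors, axis=0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g, out):
        parts = np.split(g, splits, axis=axis)
        for t, gp in zip(tensors, parts):
            if t.requires_grad:
                t._accum(gp)

    return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
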