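"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to differentiate the loss functions in this package:
elementwise arithmetic, constant-exponent powers, log/exp, axis sums with
broadcasting-aware backward, and a pass-through clip.  Loss formulas are
written once against this interface (see ``dicepp.losses._ops``) and evaluate
identically on plain numpy arrays and on :class:`Var` nodes, so the reference
and differentiable paths cannot drift apart.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    grad = np.asarray(grad)
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes broadcast from size 1
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Var:
    """A node in the computation tape: a numpy value plus a backward rule."""

    __slots__ = ("value", "grad", "_parents", "_vjps")

    # make ndarray <op> Var defer to our reflected operators instead of
    # producing an object array
    __array_ufunc__ = None

    def __init__(self, value, parents=(), vjps=()):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = None
        self._parents = parents
        self._vjps = vjps

    @property
    def shape(self):
        return self.value.shape

    # --- graph construction -------------------------------------------------
    @staticmethod
    def _lift(other):
        return other if isinstance(other, Var) else Var(np.asarray(other, dtype=np.float64))

    def __add__(self, other):
        o = self._lift(other)
        return Var(self.value + o.value, (self, o), (lambda g: g, lambda g: g))

    __radd__ = __add__

    def __sub__(self, other):
        o = self._lift(other)
        return Var(self.value - o.value, (self, o), (lambda g: g, lambda g: -g))

    def __rsub__(self, other):
        o = self._lift(other)
        return o.__sub__(self)

    def __neg__(self):
        return Var(-self.value, (self,), (lambda g: -g,))

    def __mul__(self, other):
        o = self._lift(other)
        return Var(
            self.value * o.value,
            (self, o),
            (lambda g, ov=o.value: g * ov, lambda g, sv=self.value: g * sv),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._lift(other)
        return Var(
            self.value / o.value,
            (self, o),
            (
                lambda g, ov=o.value: g / ov,
                lambda g, sv=self.value, ov=o.value: -g * sv / (ov * ov),
            ),
        )

    def __rtruediv__(self, other):
        o = self._lift(other)
        return o.__truediv__(self)

    def __pow__(self, exponent):
        if isinstance(exponent, Var):  # pragma: no cover - not needed by losses
            raise TypeError("only constant exponents are supported")
        k = float(exponent)
        if k == 1.0:
            return self
        val = self.value**k
        # d/dx x^k = k x^(k-1); with x>=0 bases and k>=1 the 0-base limit is 0
        # (numpy's 0**0 == 1 handles k==1, excluded above).
        def vjp(g, sv=self.value, k=k):
            with np.errstate(divide="ignore", invalid="ignore"):
                d = k * sv ** (k - 1.0)
            return g * np.where(np.isfinite(d), d, 0.0)

        return Var(val, (self,), (vjp,))

    # --- backward -----------------------------------------------------------
    def backward(self):
        """Accumulate d(self)/d(leaf) into ``.grad`` of every node."""
        order: list[Var] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        for node in order:
            node.grad = np.zeros_like(node.value)
        self.grad = np.ones_like(self.value)
        for node in reversed(order):
            for parent, vjp in zip(node._parents, node._vjps):
                parent.grad = parent.grad + _unbroadcast(vjp(node.grad), parent.value.shape)


# --- functional ops (dispatch on Var vs ndarray) -----------------------------

def log(x):
    if isinstance(x, Var):
        return Var(np.log(x.value), (x,), (lambda g, xv=x.value: g / xv,))
    return np.log(x)


def exp(x):
    if isinstance(x, Var):
        val = np.exp(x.value)
        return Var(val, (x,), (lambda g, v=val: g * v,))
    return np.exp(x)


def clip(x, lo, hi):
    """Clip with pass-through gradient strictly inside the bounds."""
    if isinstance(x, Var):
        val = np.clip(x.value, lo, hi)
        inside = ((x.value > lo) & (x.value < hi)).astype(np.float64)
        return Var(val, (x,), (lambda g, m=inside: g * m,))
    return np.clip(x, lo, hi)


def vsum(x, axis=None, keepdims=False):
    if isinstance(x, Var):
        val = x.value.sum(axis=axis, keepdims=keepdims)

        def vjp(g, shape=x.value.shape, axis=axis, keepdims=keepdims):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, shape)

        return Var(val, (x,), (vjp,))
    return np.asarray(x).sum(axis=axis, keepdims=keepdims)


def value_of(x):
    """Underlying numpy value of a Var, or the array itself."""
    return x.value if isinstance(x, Var) else np.asarray(x)


def softmax(z):
    """Numerically stable softmax over the last axis (Var or ndarray)."""
    zmax = np.max(value_of(z), axis=-1, keepdims=True)
    e = exp(z - zmax)
    return e / vsum(e, axis=-1, keepdims=True)
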