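"""Minimal reverse-mode automatic differentiation over numpy arrays.

The gradient-trained models in this package (concrete dropout, flipout,
mixture density networks, sparse variational GPs) need pathwise gradients
through stochastic computation graphs.  This module provides a small
tape-based engine: a :class:`Tensor` wrapping an ``ndarray``, the elementwise
and linear-algebra primitives those models use, and an Adam optimizer.

Gradients of every primitive are checked against central finite differences
in the test suite.  The engine is deliberately small: no views share storage,
broadcasting follows numpy semantics with gradients summed back to the
operand shape, and positive-definite solves/log-determinants use Cholesky
factorizations internally with the standard closed-form adjoints.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_factor, cho_solve


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, reversing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph plumbing -------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=float)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad or pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # the root may itself be a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=float)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        a, b = self, Tensor._wrap(other)
        return Tensor._make(
            a.data + b.data, (a, b),
            lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)
        return Tensor._make(
            a.data * b.data, (a, b),
            lambda g: (_unbroadcast(g * b.data, a.shape),
                       _unbroadcast(g * a.data, b.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        a, b = self, Tensor._wrap(other)
        return Tensor._make(
            a.data / b.data, (a, b),
            lambda g: (_unbroadcast(g / b.data, a.shape),
                       _unbroadcast(-g * a.data / b.data ** 2, b.shape)))

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, exponent: float):
        a = self
        e = float(exponent)
        return Tensor._make(
            a.data ** e, (a,), lambda g: (g * e * a.data ** (e - 1.0),))

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)
        an, bn = a.data.ndim, b.data.ndim

        def back(g):
            g = np.asarray(g, dtype=float)
            if an == 2 and bn == 2:
                return (g @ b.data.T, a.data.T @ g)
            if an == 2 and bn == 1:      # (n,m)@(m,) -> (n,)
                return (np.outer(g, b.data), a.data.T @ g)
            if an == 1 and bn == 2:      # (m,)@(m,k) -> (k,)
                return (b.data @ g, np.outer(a.data, g))
            return (g * b.data, g * a.data)  # (m,)@(m,) -> scalar

        return Tensor._make(a.data @ b.data, (a, b), back)

    def __getitem__(self, idx):
        a = self

        def back(g):
            out = np.zeros_like(a.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(a.data[idx], (a,), back)

    # -- shape ops ------------------------------------------------------------
    @property
    def T(self):
        a = self
        return Tensor._make(a.data.T, (a,), lambda g: (g.T,))

    def reshape(self, *shape):
        a = self
        return Tensor._make(a.data.reshape(*shape), (a,),
                            lambda g: (g.reshape(a.shape),))

    def sum(self, axis=None, keepdims=False):
        a = self

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, a.shape).copy(),)
            g2 = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(g2, a.shape).copy(),)

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities ------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * out_data,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    def sqrt(self):
        return self ** 0.5

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)
        return Tensor._make(out_data, (a,), lambda g: (g * (1 - out_data ** 2),))

    def relu(self):
        a = self
        mask = (a.data > 0).astype(float)
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,),
                            lambda g: (g * out_data * (1 - out_data),))

    def softplus(self):
        # log(1 + exp(x)), computed stably; derivative is sigmoid(x)
        a = self
        out_data = np.logaddexp(0.0, a.data)
        sig = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out_data, (a,), lambda g: (g * sig,))


# -- free functions ----------------------------------------------------------

def concat(tensors, axis=0):
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis),
                        tuple(tensors), back)


def logsumexp(x: Tensor, axis=-1, keepdims=False):
    """Numerically stable log-sum-exp built from primitives.

    The max shift is treated as a constant, which leaves gradients exact.
    """
    shift = np.max(x.data, axis=axis, keepdims=True)
    shifted = x - shift
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + shift
    if not keepdims:
        out = out.reshape(tuple(np.delete(out.data.shape, axis)))
    return out


def solve_psd(a: Tensor, b: Tensor) -> Tensor:
    """X = A^{-1} B for symmetric positive-definite A, via Cholesky.

    Adjoints: dB = A^{-1} G, dA = -sym(dB X^T).
    """
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    c, low = cho_factor(a.data, lower=True)
    b2 = b.data if b.data.ndim > 1 else b.data[:, None]
    x = cho_solve((c, low), b2)

    def back(g):
        g2 = g if g.ndim > 1 else g[:, None]
        gb = cho_solve((c, low), g2)
        ga = -gb @ x.T
        ga = 0.5 * (ga + ga.T)
        return (ga, gb.reshape(b.shape))

    return Tensor._make(x.reshape(b.shape) if b.data.ndim == 1 else x,
                        (a, b), back)


def logdet_psd(a: Tensor) -> Tensor:
    """log|A| for symmetric positive-definite A; adjoint is g * A^{-1}."""
    a = Tensor._wrap(a)
    c, low = cho_factor(a.data, lower=True)
    val = 2.0 * np.sum(np.log(np.diag(c)))

    def back(g):
        inv = cho_solve((c, low), np.eye(a.data.shape[0]))
        return (float(g) * 0.5 * (inv + inv.T),)

    return Tensor._make(val, (a,), back)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

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
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
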