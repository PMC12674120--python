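"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small, vectorized autodiff engine providing exactly the
primitives the variational objective needs: arithmetic, matmul, gather /
scatter-add, the Gaussian CDF / quantile pair used for reparameterized
truncated-normal sampling, and a log-scaled modified Bessel function of the
first kind for Rice log-densities.

Every public function dispatches on its inputs: called with plain arrays it
returns a plain array (so the same density code serves the NumPy-facing API),
called with at least one :class:`Tensor` it builds the backward graph.
Gradients are plain float64 arrays accumulated on ``Tensor.grad``.
"""

from __future__ import annotations

import numpy as np
from scipy import special as _sp

__all__ = [
    "Tensor", "Adam", "astensor", "add", "sub", "mul", "div", "neg", "power",
    "exp", "log", "log1p", "sqrt", "square", "tanh", "sigmoid", "softplus",
    "logaddexp", "maximum", "clip", "where", "total", "mean", "matmul",
    "gather", "reshape", "ndtr", "log_ndtr", "ndtri", "log_i0",
]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _is_t(x) -> bool:
    return isinstance(x, Tensor)


def _val(x):
    return x.value if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    grad = np.asarray(grad, dtype=float)
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """Array node in the backward graph."""

    __slots__ = ("value", "grad", "_parents", "_vjp")

    # make numpy defer to the reflected operators instead of building
    # object arrays elementwise
    __array_ufunc__ = None

    def __init__(self, value, _parents=(), _vjp=None):
        self.value = np.asarray(value, dtype=float)
        self.grad = None
        self._parents = _parents
        self._vjp = _vjp

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.value.shape

    @property
    def ndim(self):
        return self.value.ndim

    def item(self) -> float:
        return float(self.value)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.value.shape}, value={self.value!r})"

    # -- autograd ----------------------------------------------------------
    def backward(self) -> None:
        """Accumulate d(self)/d(leaf) into ``.grad`` of every ancestor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.value)
        for node in reversed(topo):
            if node._vjp is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._vjp(node.grad)):
                if g is None:
                    continue
                g = _unbroadcast(g, parent.value.shape)
                parent.grad = g if parent.grad is None else parent.grad + g

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(other, self)

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(other, self)

    def __neg__(self):
        return neg(self)

    def __pow__(self, p):
        return power(self, p)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    if not (_is_t(a) or _is_t(b)):
        return np.asarray(a, dtype=float) + np.asarray(b, dtype=float)
    a, b = astensor(a), astensor(b)
    return Tensor(a.value + b.value, (a, b), lambda g: (g, g))


def sub(a, b):
    if not (_is_t(a) or _is_t(b)):
        return np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    a, b = astensor(a), astensor(b)
    return Tensor(a.value - b.value, (a, b), lambda g: (g, -g))


def mul(a, b):
    if not (_is_t(a) or _is_t(b)):
        return np.asarray(a, dtype=float) * np.asarray(b, dtype=float)
    a, b = astensor(a), astensor(b)
    return Tensor(a.value * b.value, (a, b), lambda g: (g * b.value, g * a.value))


def div(a, b):
    if not (_is_t(a) or _is_t(b)):
        return np.asarray(a, dtype=float) / np.asarray(b, dtype=float)
    a, b = astensor(a), astensor(b)
    v = a.value / b.value
    return Tensor(v, (a, b), lambda g: (g / b.value, -g * v / b.value))


def neg(a):
    if not _is_t(a):
        return -np.asarray(a, dtype=float)
    return Tensor(-a.value, (a,), lambda g: (-g,))


def power(a, p: float):
    """``a ** p`` for a constant exponent ``p``."""
    if not _is_t(a):
        return np.asarray(a, dtype=float) ** p
    v = a.value ** p
    return Tensor(v, (a,), lambda g: (g * p * a.value ** (p - 1),))


# ---------------------------------------------------------------------------
# elementwise transcendental
# ---------------------------------------------------------------------------

def exp(a):
    if not _is_t(a):
        return np.exp(np.asarray(a, dtype=float))
    v = np.exp(a.value)
    return Tensor(v, (a,), lambda g: (g * v,))


def log(a):
    if not _is_t(a):
        return np.log(np.asarray(a, dtype=float))
    return Tensor(np.log(a.value), (a,), lambda g: (g / a.value,))


def log1p(a):
    if not _is_t(a):
        return np.log1p(np.asarray(a, dtype=float))
    return Tensor(np.log1p(a.value), (a,), lambda g: (g / (1.0 + a.value),))


def sqrt(a):
    if not _is_t(a):
        return np.sqrt(np.asarray(a, dtype=float))
    v = np.sqrt(a.value)
    return Tensor(v, (a,), lambda g: (0.5 * g / v,))


def square(a):
    if not _is_t(a):
        return np.square(np.asarray(a, dtype=float))
    return Tensor(np.square(a.value), (a,), lambda g: (2.0 * g * a.value,))


def tanh(a):
    if not _is_t(a):
        return np.tanh(np.asarray(a, dtype=float))
    v = np.tanh(a.value)
    return Tensor(v, (a,), lambda g: (g * (1.0 - v * v),))


def sigmoid(a):
    if not _is_t(a):
        return _sp.expit(np.asarray(a, dtype=float))
    v = _sp.expit(a.value)
    return Tensor(v, (a,), lambda g: (g * v * (1.0 - v),))


def softplus(a):
    """log(1 + exp(a)), overflow-safe."""
    if not _is_t(a):
        x = np.asarray(a, dtype=float)
        return np.logaddexp(0.0, x)
    v = np.logaddexp(0.0, a.value)
    return Tensor(v, (a,), lambda g: (g * _sp.expit(a.value),))


def logaddexp(a, b):
    if not (_is_t(a) or _is_t(b)):
        return np.logaddexp(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    a, b = astensor(a), astensor(b)
    v = np.logaddexp(a.value, b.value)
    return Tensor(v, (a, b),
                  lambda g: (g * np.exp(a.value - v), g * np.exp(b.value - v)))


def maximum(a, b):
    """Elementwise max; the subgradient routes to ``a`` on ties."""
    if not (_is_t(a) or _is_t(b)):
        return np.maximum(np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    a, b = astensor(a), astensor(b)
    take_a = a.value >= b.value
    v = np.where(take_a, a.value, b.value)
    return Tensor(v, (a, b), lambda g: (g * take_a, g * ~take_a))


def clip(a, lo: float, hi: float):
    """Clamp to [lo, hi]; gradient is zero outside the interval."""
    if not _is_t(a):
        return np.clip(np.asarray(a, dtype=float), lo, hi)
    inside = (a.value >= lo) & (a.value <= hi)
    return Tensor(np.clip(a.value, lo, hi), (a,), lambda g: (g * inside,))


def where(cond, a, b):
    """Select with a constant boolean mask (``cond`` is never differentiated)."""
    cond = np.asarray(cond, dtype=bool)
    if not (_is_t(a) or _is_t(b)):
        return np.where(cond, np.asarray(a, dtype=float), np.asarray(b, dtype=float))
    a, b = astensor(a), astensor(b)
    v = np.where(cond, a.value, b.value)
    return Tensor(v, (a, b), lambda g: (g * cond, g * ~cond))


# ---------------------------------------------------------------------------
# reductions / shape / linear algebra
# ---------------------------------------------------------------------------

def total(a, axis=None, keepdims: bool = False):
    """Sum (named to avoid shadowing the builtin)."""
    if not _is_t(a):
        return np.sum(np.asarray(a, dtype=float), axis=axis, keepdims=keepdims)
    v = np.sum(a.value, axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g, dtype=float)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.value.shape).copy(),)

    return Tensor(v, (a,), vjp)


def mean(a, axis=None, keepdims: bool = False):
    if not _is_t(a):
        return np.mean(np.asarray(a, dtype=float), axis=axis, keepdims=keepdims)
    n = a.value.size if axis is None else a.value.shape[axis]
    return div(total(a, axis=axis, keepdims=keepdims), float(n))


def matmul(a, b):
    """2-D matrix product."""
    if not (_is_t(a) or _is_t(b)):
        return np.asarray(a, dtype=float) @ np.asarray(b, dtype=float)
    a, b = astensor(a), astensor(b)
    return Tensor(a.value @ b.value, (a, b),
                  lambda g: (g @ b.value.T, a.value.T @ g))


def gather(a, idx, axis: int = 0):
    """``np.take`` along ``axis`` with scatter-add backward."""
    if not _is_t(a):
        return np.take(np.asarray(a, dtype=float), idx, axis=axis)
    idx = np.asarray(idx) if not np.isscalar(idx) else idx
    v = np.take(a.value, idx, axis=axis)

    def vjp(g):
        out = np.zeros_like(a.value)
        sl = (slice(None),) * axis + (idx,)
        np.add.at(out, sl, g)
        return (out,)

    return Tensor(v, (a,), vjp)


def reshape(a, shape):
    if not _is_t(a):
        return np.reshape(np.asarray(a, dtype=float), shape)
    old = a.value.shape
    return Tensor(a.value.reshape(shape), (a,),
                  lambda g: (np.asarray(g).reshape(old),))


# ---------------------------------------------------------------------------
# special functions
# ---------------------------------------------------------------------------

def ndtr(a):
    """Standard normal CDF Φ."""
    if not _is_t(a):
        return _sp.ndtr(np.asarray(a, dtype=float))
    v = _sp.ndtr(a.value)
    pdf = np.exp(-0.5 * a.value ** 2 - _LOG_SQRT_2PI)
    return Tensor(v, (a,), lambda g: (g * pdf,))


def log_ndtr(a):
    """log Φ, stable for very negative arguments."""
    if not _is_t(a):
        return _sp.log_ndtr(np.asarray(a, dtype=float))
    v = _sp.log_ndtr(a.value)
    # d/dx log Φ(x) = φ(x)/Φ(x)
    ratio = np.exp(-0.5 * a.value ** 2 - _LOG_SQRT_2PI - v)
    return Tensor(v, (a,), lambda g: (g * ratio,))


def ndtri(a):
    """Standard normal quantile Φ⁻¹; input must lie strictly in (0, 1)."""
    if not _is_t(a):
        return _sp.ndtri(np.asarray(a, dtype=float))
    v = _sp.ndtri(a.value)
    # dΦ⁻¹/dp = 1/φ(Φ⁻¹(p))
    deriv = np.exp(0.5 * v ** 2 + _LOG_SQRT_2PI)
    return Tensor(v, (a,), lambda g: (g * deriv,))


def log_i0(a):
    """log I₀, via the exponentially scaled Bessel so large arguments
    cannot overflow; even in its argument."""
    if not _is_t(a):
        x = np.abs(np.asarray(a, dtype=float))
        return np.log(_sp.i0e(x)) + x
    x = np.abs(a.value)
    v = np.log(_sp.i0e(x)) + x
    # d/dz log I0(z) = I1(z)/I0(z), with the parity sign
    ratio = _sp.i1e(x) / _sp.i0e(x) * np.sign(a.value)
    return Tensor(v, (a,), lambda g: (g * ratio,))


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient ascent/descent on a list of leaf Tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        """Descend along the accumulated gradients."""
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite differences of a scalar function of one array (test aid)."""
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2.0 * eps)
    return g
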