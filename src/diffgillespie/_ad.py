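"""Forward-mode automatic differentiation on numpy arrays.

The smoothed Gillespie stepper needs derivatives of simulation outputs with
respect to a handful of kinetic parameters (never more than ~7).  Forward-mode
dual numbers are the natural fit at that parameter count: every array carries a
tangent block with one trailing axis of length ``n_params``, and elementary
operations propagate Jacobian-vector products exactly.

Only the operations the simulator actually uses are implemented.  All free
functions (`log`, `exp`, `sigmoid`, ...) accept either a plain ndarray or a
:class:`Dual` so the simulation code is written once and runs with or without
gradient tracking.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = [
    "Dual",
    "seed_duals",
    "value",
    "tangent",
    "log",
    "exp",
    "sqrt",
    "sigmoid",
    "softplus",
    "where",
    "cumsum",
    "asum",
    "amean",
    "stack",
    "unsqueeze",
    "dot_const",
    "smooth_clamp",
]


def _bt(tan: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Broadcast a tangent block to match a (possibly broadcast) value shape."""
    target = np.shape(val) + (tan.shape[-1],)
    if tan.shape == target:
        return tan
    return np.broadcast_to(tan, target)


class Dual:
    """An array paired with its Jacobian w.r.t. a fixed parameter vector.

    ``val`` has an arbitrary shape ``s``; ``tan`` has shape ``s + (P,)`` where
    ``P`` is the number of tracked parameters.
    """

    __slots__ = ("val", "tan")

    # make numpy defer binary ops to the reflected Dual methods
    __array_ufunc__ = None

    def __init__(self, val, tan):
        self.val = np.asarray(val, dtype=float)
        self.tan = np.asarray(tan, dtype=float)
        if self.tan.shape[:-1] != self.val.shape:
            self.tan = _bt(self.tan, self.val)

    # -- housekeeping --------------------------------------------------
    @property
    def shape(self):
        return self.val.shape

    @property
    def n_params(self) -> int:
        return self.tan.shape[-1]

    def copy(self) -> "Dual":
        return Dual(self.val.copy(), self.tan.copy())

    def __getitem__(self, idx) -> "Dual":
        if isinstance(idx, tuple):
            return Dual(self.val[idx], self.tan[idx + (slice(None),)])
        return Dual(self.val[idx], self.tan[idx])

    def __repr__(self):
        return f"Dual(val={self.val!r}, n_params={self.n_params})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val + other.val, self.tan + other.tan)
        return Dual(self.val + other, _bt(self.tan, self.val + other))

    __radd__ = __add__

    def __neg__(self):
        return Dual(-self.val, -self.tan)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Dual) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Dual):
            return Dual(
                self.val * other.val,
                self.tan * other.val[..., None] + other.tan * self.val[..., None],
            )
        other = np.asarray(other, dtype=float)
        return Dual(self.val * other, _bt(self.tan * other[..., None], self.val * other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Dual):
            inv = 1.0 / other.val
            val = self.val * inv
            tan = (self.tan - other.tan * val[..., None]) * inv[..., None]
            return Dual(val, tan)
        other = np.asarray(other, dtype=float)
        return Dual(self.val / other, _bt(self.tan / other[..., None], self.val / other))

    def __rtruediv__(self, other):
        other = np.asarray(other, dtype=float)
        val = other / self.val
        tan = -self.tan * (val / self.val)[..., None]
        return Dual(val, _bt(tan, val))

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("Dual ** only supports scalar exponents")
        val = self.val**p
        return Dual(val, self.tan * (p * self.val ** (p - 1))[..., None])

    # comparisons fall through to values (used for masks; masks are not
    # differentiated — that is the pathwise-estimator convention)
    def __lt__(self, other):
        return self.val < value(other)

    def __le__(self, other):
        return self.val <= value(other)

    def __gt__(self, other):
        return self.val > value(other)

    def __ge__(self, other):
        return self.val >= value(other)


def value(x):
    """Value part of ``x`` (identity for plain arrays/scalars)."""
    return x.val if isinstance(x, Dual) else x


def tangent(x, n_params: int | None = None):
    """Tangent block of ``x``; zeros for a plain array (``n_params`` required)."""
    if isinstance(x, Dual):
        return x.tan
    if n_params is None:
        raise ValueError("n_params required for non-dual input")
    return np.zeros(np.shape(x) + (n_params,))


def seed_duals(values: dict, free: list[str], log_space: bool = False) -> dict:
    """Lift a parameter mapping to duals, tracking the names in ``free``.

    With ``log_space=True`` the tangents are taken w.r.t. ``log(theta)``,
    i.e. d theta / d log theta = theta, so downstream gradients come out in
    log-parameter coordinates (the coordinates the optimizer works in).
    """
    P = len(free)
    out = {}
    for name, v in values.items():
        if name in free:
            i = free.index(name)
            t = np.zeros(P)
            t[i] = v if log_space else 1.0
            out[name] = Dual(np.asarray(v, dtype=float), t)
        else:
            out[name] = float(v)
    return out


# -- elementwise functions --------------------------------------------


def log(x):
    if isinstance(x, Dual):
        return Dual(np.log(x.val), x.tan / x.val[..., None])
    return np.log(x)


def exp(x):
    if isinstance(x, Dual):
        v = np.exp(x.val)
        return Dual(v, x.tan * v[..., None])
    return np.exp(x)


def sqrt(x):
    if isinstance(x, Dual):
        v = np.sqrt(x.val)
        return Dual(v, x.tan / (2.0 * v)[..., None])
    return np.sqrt(x)


def sigmoid(x):
    """Numerically stable logistic function."""
    if isinstance(x, Dual):
        s = expit(x.val)
        return Dual(s, x.tan * (s * (1.0 - s))[..., None])
    return expit(x)


def softplus(x):
    """log(1 + e^x), overflow-safe."""
    if isinstance(x, Dual):
        v = np.maximum(x.val, 0.0) + np.log1p(np.exp(-np.abs(x.val)))
        return Dual(v, x.tan * expit(x.val)[..., None])
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def smooth_clamp(x, sharpness: float = 1e3):
    """Smooth projection onto [0, inf): softplus(k*x)/k.

    Behaves as identity for x >> 1/k and as 0 for x << -1/k while keeping a
    nonzero derivative everywhere, so gradients survive transient undershoots
    below zero.
    """
    return softplus(x * sharpness) * (1.0 / sharpness)


def where(cond, a, b):
    cond = np.asarray(cond)
    if isinstance(a, Dual) or isinstance(b, Dual):
        P = a.n_params if isinstance(a, Dual) else b.n_params
        av, bv = value(a), value(b)
        val = np.where(cond, av, bv)
        at = tangent(a, P) if not isinstance(a, Dual) else a.tan
        bt = tangent(b, P) if not isinstance(b, Dual) else b.tan
        at = _bt(at, val)
        bt = _bt(bt, val)
        return Dual(val, np.where(cond[..., None], at, bt))
    return np.where(cond, a, b)


# -- reductions / shaping ---------------------------------------------


def _norm_axis(axis, ndim):
    if axis is None:
        return tuple(range(ndim))
    if np.isscalar(axis):
        axis = (axis,)
    return tuple(a % ndim for a in axis)


def asum(x, axis=None):
    if isinstance(x, Dual):
        ax = _norm_axis(axis, x.val.ndim)
        return Dual(x.val.sum(axis=ax), x.tan.sum(axis=ax))
    return np.sum(x, axis=axis)


def amean(x, axis=None):
    if isinstance(x, Dual):
        ax = _norm_axis(axis, x.val.ndim)
        return Dual(x.val.mean(axis=ax), x.tan.mean(axis=ax))
    return np.mean(x, axis=axis)


def cumsum(x, axis=-1):
    if isinstance(x, Dual):
        ax = axis % x.val.ndim
        return Dual(np.cumsum(x.val, axis=ax), np.cumsum(x.tan, axis=ax))
    return np.cumsum(x, axis=axis)


def stack(xs, axis=-1):
    """Stack a sequence of arrays/duals along a new axis (of the value)."""
    if any(isinstance(x, Dual) for x in xs):
        P = next(x.n_params for x in xs if isinstance(x, Dual))
        shape = np.broadcast_shapes(*(np.shape(value(x)) for x in xs))
        vals = [np.broadcast_to(np.asarray(value(x), dtype=float), shape) for x in xs]
        tans = [
            _bt(x.tan, np.empty(shape)) if isinstance(x, Dual) else np.zeros(shape + (P,))
            for x in xs
        ]
        ax = axis % (len(shape) + 1)
        return Dual(np.stack(vals, axis=ax), np.stack(tans, axis=ax))
    return np.stack(np.broadcast_arrays(*xs), axis=axis)


def unsqueeze(x, axis=-1):
    """Insert a length-1 axis into the *value* shape (tangent axis stays last)."""
    if isinstance(x, Dual):
        vax = axis % (x.val.ndim + 1)
        return Dual(np.expand_dims(x.val, vax), np.expand_dims(x.tan, vax))
    return np.expand_dims(np.asarray(x), axis)


def dot_const(w, m: np.ndarray):
    """Contract the last value-axis of ``w`` with constant matrix ``m``.

    value: ``w @ m``; tangent contracted over the same axis.
    """
    m = np.asarray(m, dtype=float)
    if isinstance(w, Dual):
        return Dual(w.val @ m, np.einsum("...np,nk->...kp", w.tan, m))
    return w @ m
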