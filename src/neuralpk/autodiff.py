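"""Reverse-mode automatic differentiation over numpy arrays.

The training objectives differentiate through the closed-form two-compartment
solution, the branch networks, and the covariance/variational
parameterizations.  This module provides the tape: a :class:`Tensor` wrapping
an ndarray, overloaded elementwise/linear-algebra operations that record
vector-Jacobian products, and :meth:`Tensor.backward` for the reverse sweep.

A small forward-mode :class:`Dual` layer (two tangent slots) is layered on
top; it propagates derivatives with respect to two chosen scalars (here the
clearance and central volume) through code written against the dispatching
functions below, with entries that may themselves be Tensors.  This is what
gives the eta-Jacobians required by the FO/FOCE linearizations while keeping
those Jacobians differentiable with respect to the population parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit as _expit

__all__ = [
    "Tensor",
    "astensor",
    "parameter",
    "stop_gradient",
    "exp",
    "log",
    "sqrt",
    "tanh",
    "sigmoid",
    "softplus",
    "swish",
    "matmul",
    "stack",
    "concatenate",
    "inv",
    "logdet",
    "Dual",
    "grad_check",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node on the differentiation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    # defer all numpy binary ops to the reflected methods below
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        # parents: sequence of (Tensor, vjp callable)
        self._parents = tuple(parents)

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor({self.data!r}, requires_grad={self.requires_grad})"

    # -- reverse sweep --------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node._parents:
                if id(parent) not in seen:
                    stack.append((parent, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            for parent, vjp in node._parents:
                pg = vjp(g)
                if pg is None:
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    # binary ops defer to Dual (forward-mode wins when types mix)
    def __add__(self, other):
        if isinstance(other, Dual):
            return NotImplemented
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, Dual):
            return NotImplemented
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        if isinstance(other, Dual):
            return NotImplemented
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(astensor(other), mul(self, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, Dual):
            return NotImplemented
        return divide(self, other)

    def __rtruediv__(self, other):
        return divide(astensor(other), self)

    def __pow__(self, exponent):
        return power(self, exponent)

    def __matmul__(self, other):
        return matmul(self, other)

    def __rmatmul__(self, other):
        return matmul(astensor(other), self)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes if axes else None)

    @property
    def mT(self):
        """Swap the last two axes (batched matrix transpose)."""
        axes = list(range(self.ndim))
        axes[-1], axes[-2] = axes[-2], axes[-1]
        return transpose(self, tuple(axes))

    def item(self):
        return float(self.data)


def astensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64), requires_grad=True)


def _needs_tape(*xs) -> bool:
    return any(isinstance(x, Tensor) and (x.requires_grad or x._parents) for x in xs)


def _make(data, parents):
    # Drop the tape for constant subexpressions.
    parents = tuple((p, v) for p, v in parents if p.requires_grad or p._parents)
    return Tensor(data, parents=parents)


# -- primitive ops -----------------------------------------------------------

def add(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data + b.data
    return _make(
        out_data,
        [
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ],
    )


def mul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data * b.data
    return _make(
        out_data,
        [
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ],
    )


def divide(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data / b.data
    return _make(
        out_data,
        [
            (a, lambda g: _unbroadcast(g / b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(-g * out_data / b.data, b.data.shape)),
        ],
    )


def power(a, exponent: float):
    a = astensor(a)
    e = float(exponent)
    out_data = a.data**e
    return _make(out_data, [(a, lambda g: g * e * a.data ** (e - 1.0))])


def _unary(a, data, local):
    a = astensor(a)
    return _make(data, [(a, lambda g: g * local)])


def exp(x):
    if not isinstance(x, Tensor):
        return np.exp(x)
    d = np.exp(x.data)
    return _unary(x, d, d)


def log(x):
    if not isinstance(x, Tensor):
        return np.log(x)
    return _unary(x, np.log(x.data), 1.0 / x.data)


def sqrt(x):
    if not isinstance(x, Tensor):
        return np.sqrt(x)
    d = np.sqrt(x.data)
    return _unary(x, d, 0.5 / d)


def tanh(x):
    if not isinstance(x, Tensor):
        return np.tanh(x)
    d = np.tanh(x.data)
    return _unary(x, d, 1.0 - d * d)


def sigmoid(x):
    if not isinstance(x, Tensor):
        return _expit(x)
    d = _expit(x.data)
    return _unary(x, d, d * (1.0 - d))


def softplus(x):
    """log(1 + exp(x)), overflow-safe."""
    if not isinstance(x, Tensor):
        return np.logaddexp(0.0, x)
    return _unary(x, np.logaddexp(0.0, x.data), _expit(x.data))


def swish(x):
    """x * sigmoid(x) — the smooth hidden-layer activation."""
    if not isinstance(x, Tensor):
        return x * _expit(x)
    return mul(x, sigmoid(x))


def tsum(a, axis=None, keepdims=False):
    a = astensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        if axis is None:
            return np.broadcast_to(g, a.data.shape).copy()
        if not keepdims:
            g = np.expand_dims(g, axis)
        return np.broadcast_to(g, a.data.shape).copy()

    return _make(out_data, [(a, vjp)])


def reshape(a, shape):
    a = astensor(a)
    return _make(a.data.reshape(shape), [(a, lambda g: g.reshape(a.data.shape))])


def transpose(a, axes=None):
    a = astensor(a)
    if axes is None:
        axes = tuple(reversed(range(a.ndim)))
    inverse = np.argsort(axes)
    return _make(a.data.transpose(axes), [(a, lambda g: g.transpose(inverse))])


def take(a, idx):
    a = astensor(a)

    def vjp(g):
        out = np.zeros_like(a.data)
        np.add.at(out, idx, g)
        return out

    return _make(a.data[idx], [(a, vjp)])


def stack(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    parents = []
    for i, t in enumerate(tensors):
        parents.append((t, lambda g, i=i: np.take(g, i, axis=axis)))
    return _make(out_data, parents)


def concatenate(tensors, axis=0):
    tensors = [astensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    parents = []
    for i, t in enumerate(tensors):
        sl = [slice(None)] * out_data.ndim
        sl[axis] = slice(offsets[i], offsets[i + 1])
        parents.append((t, lambda g, sl=tuple(sl): g[sl]))
    return _make(out_data, parents)


def matmul(a, b):
    a, b = astensor(a), astensor(b)
    out_data = a.data @ b.data

    def vjp_a(g):
        if b.ndim == 1:
            ga = np.multiply.outer(g, b.data) if a.ndim > 1 else g * b.data
        else:
            ga = g @ np.swapaxes(b.data, -1, -2)
        return _unbroadcast(ga, a.data.shape)

    def vjp_b(g):
        if a.ndim == 1:
            gb = np.multiply.outer(a.data, g) if b.ndim > 1 else a.data * g
        else:
            gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(gb, b.data.shape)

    return _make(out_data, [(a, vjp_a), (b, vjp_b)])


def inv(a):
    """Batched matrix inverse with the standard VJP −A⁻ᵀ ḡ A⁻ᵀ."""
    a = astensor(a)
    inv_data = np.linalg.inv(a.data)

    def vjp(g):
        it = np.swapaxes(inv_data, -1, -2)
        return -it @ g @ it

    return _make(inv_data, [(a, vjp)])


def logdet(a):
    """Batched log|det A| for positive-definite A; VJP is A⁻ᵀ."""
    a = astensor(a)
    sign, ld = np.linalg.slogdet(a.data)
    if np.any(sign <= 0):
        raise np.linalg.LinAlgError("logdet requires positive determinant")

    def vjp(g):
        return g[..., None, None] * np.swapaxes(np.linalg.inv(a.data), -1, -2)

    return _make(ld, [(a, vjp)])


def stop_gradient(x):
    """Detach a value from the tape (the path-derivative estimator's tool)."""
    if isinstance(x, Tensor):
        return Tensor(x.data.copy())
    return np.asarray(x, dtype=np.float64)


# -- forward-mode layer ------------------------------------------------------


class Dual:
    """Value with two tangent slots, for Jacobians w.r.t. two scalars.

    Entries may be ndarrays or Tensors; all operations route through the
    dispatching functions above, so tangents stay on the reverse-mode tape
    when the inputs do.
    """

    __slots__ = ("val", "d1", "d2")

    __array_ufunc__ = None

    def __init__(self, val, d1=0.0, d2=0.0):
        self.val = val
        self.d1 = d1
        self.d2 = d2

    def __add__(self, other):
        if isinstance(other, Dual):
            return Dual(self.val + other.val, self.d1 + other.d1, self.d2 + other.d2)
        return Dual(self.val + other, self.d1, self.d2)

    __radd__ = __add__

    def __neg__(self):
        return Dual(-self.val, -self.d1, -self.d2)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Dual) else -1.0 * other)

    def __rsub__(self, other):
        return (-self) + other

    def __mul__(self, other):
        if isinstance(other, Dual):
            return Dual(
                self.val * other.val,
                self.d1 * other.val + self.val * other.d1,
                self.d2 * other.val + self.val * other.d2,
            )
        return Dual(self.val * other, self.d1 * other, self.d2 * other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Dual):
            inv_v = 1.0 / other.val
            q = self.val * inv_v
            return Dual(
                q,
                (self.d1 - q * other.d1) * inv_v,
                (self.d2 - q * other.d2) * inv_v,
            )
        return Dual(self.val / other, self.d1 / other, self.d2 / other)

    def __rtruediv__(self, other):
        inv_v = 1.0 / self.val
        q = other * inv_v
        return Dual(q, -q * self.d1 * inv_v, -q * self.d2 * inv_v)

    def __pow__(self, e):
        e = float(e)
        local = e * self.val ** (e - 1.0)
        return Dual(self.val**e, local * self.d1, local * self.d2)


def dual_exp(x):
    if isinstance(x, Dual):
        v = exp(x.val)
        return Dual(v, v * x.d1, v * x.d2)
    return exp(x)


def dual_sqrt(x):
    if isinstance(x, Dual):
        v = sqrt(x.val)
        local = 0.5 / v
        return Dual(v, local * x.d1, local * x.d2)
    return sqrt(x)


# -- finite-difference check (used by the test-suite) ------------------------


def grad_check(fn, params, eps=1e-6):
    """Max relative error between tape gradients and central differences."""
    tensors = [parameter(p) for p in params]
    out = fn(*tensors)
    out.backward()
    worst = 0.0
    for t in tensors:
        g_num = np.zeros_like(t.data)
        flat = t.data.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + eps
            hi = float(fn(*[Tensor(u.data) for u in tensors]).data)
            flat[i] = orig - eps
            lo = float(fn(*[Tensor(u.data) for u in tensors]).data)
            flat[i] = orig
            g_num.ravel()[i] = (hi - lo) / (2 * eps)
        g = np.zeros_like(t.data) if t.grad is None else t.grad
        denom = np.maximum(np.abs(g_num), 1.0)
        worst = max(worst, float(np.max(np.abs(g - g_num) / denom)))
    return worst
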