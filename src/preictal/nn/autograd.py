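"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine sufficient for the models in this package:
2-D convolution (via im2col + GEMM), batch normalisation composed from
elementwise ops, the LSTM gate arithmetic, and the contrastive /
cross-entropy losses.  Every op records a closure computing the
vector-Jacobian product of its inputs; ``Tensor.backward`` walks the
graph in reverse topological order.

Gradients are accumulated in ``Tensor.grad`` only for tensors created
with ``requires_grad=True`` (parameters) or depending on one.  Wrapping
evaluation code in ``no_grad()`` skips graph construction entirely.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager disabling graph construction (for evaluation)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over broadcast axes so it matches ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _needs_graph(self) -> bool:
        return _grad_enabled and (self.requires_grad or self._parents != ())

    def backward(self):
        """Accumulate gradients of ``self`` (summed to a scalar) into leaves."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # free the tape
        for t in topo:
            t._backward = None
            t._parents = ()

    # ------------------------------------------------------------- primitives
    def _coerce(self, other) -> "Tensor":
        """Wrap a non-Tensor operand, keeping this tensor's float dtype for
        plain Python scalars so float32 graphs stay float32."""
        if isinstance(other, Tensor):
            return other
        if isinstance(other, (int, float)):
            return Tensor(np.asarray(other, dtype=self.data.dtype))
        return Tensor(other)

    def _binary(self, other, out_data, vjp_self, vjp_other):
        out = Tensor(out_data)
        if _grad_enabled and (self._needs_graph() or other._needs_graph()):
            out._parents = (self, other)

            def bwd(g):
                if self._needs_graph():
                    _accum(self, vjp_self(g))
                if other._needs_graph():
                    _accum(other, vjp_other(g))

            out._backward = bwd
        return out

    def _unary(self, out_data, vjp):
        out = Tensor(out_data)
        if self._needs_graph():
            out._parents = (self,)
            out._backward = lambda g: _accum(self, vjp(g))
        return out

    def __add__(self, other):
        o = self._coerce(other)
        return self._binary(
            o, self.data + o.data,
            lambda g: _unbroadcast(g, self.data.shape),
            lambda g: _unbroadcast(g, o.data.shape))

    __radd__ = __add__

    def __neg__(self):
        return self._unary(-self.data, lambda g: -g)

    def __sub__(self, other):
        o = self._coerce(other)
        return self._binary(
            o, self.data - o.data,
            lambda g: _unbroadcast(g, self.data.shape),
            lambda g: _unbroadcast(-g, o.data.shape))

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        o = self._coerce(other)
        return self._binary(
            o, self.data * o.data,
            lambda g: _unbroadcast(g * o.data, self.data.shape),
            lambda g: _unbroadcast(g * self.data, o.data.shape))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return self._binary(
            o, self.data / o.data,
            lambda g: _unbroadcast(g / o.data, self.data.shape),
            lambda g: _unbroadcast(-g * self.data / (o.data * o.data),
                                   o.data.shape))

    def matmul(self, other):
        o = self._coerce(other)
        return self._binary(
            o, self.data @ o.data,
            lambda g: g @ o.data.T,
            lambda g: self.data.T @ g)

    __matmul__ = matmul

    def relu(self):
        mask = self.data > 0
        return self._unary(np.where(mask, self.data, 0.0),
                           lambda g: g * mask)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        return self._unary(s, lambda g: g * s * (1.0 - s))

    def tanh(self):
        t = np.tanh(self.data)
        return self._unary(t, lambda g: g * (1.0 - t * t))

    def exp(self):
        e = np.exp(self.data)
        return self._unary(e, lambda g: g * e)

    def log(self):
        return self._unary(np.log(self.data), lambda g: g / self.data)

    def sqrt(self):
        r = np.sqrt(self.data)
        return self._unary(r, lambda g: g / (2.0 * r))

    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            if not keepdims:
                g = np.expand_dims(g, axis)
            return np.broadcast_to(g, self.data.shape).copy()

        return self._unary(out_data, vjp)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        orig = self.data.shape
        return self._unary(self.data.reshape(shape),
                           lambda g: g.reshape(orig))

    def transpose(self, *axes):
        axes = axes or None
        if axes is not None and len(axes) == 1 and isinstance(axes[0], tuple):
            axes = axes[0]
        if axes is None:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        return self._unary(self.data.transpose(axes),
                           lambda g: g.transpose(inv))

    @property
    def T(self):
        return self.transpose()


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = np.asarray(g, dtype=t.data.dtype).copy()
    else:
        t.grad += g


# ---------------------------------------------------------------- functionals

def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if _grad_enabled and any(t._needs_graph() for t in tensors):
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]
        out._parents = tuple(tensors)

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t._needs_graph():
                    _accum(t, piece)

        out._backward = bwd
    return out


def logsumexp(t: Tensor, axis: int = -1) -> Tensor:
    m = t.data.max(axis=axis, keepdims=True)
    e = np.exp(t.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out_data = np.squeeze(m + np.log(s), axis=axis)
    soft = e / s

    def vjp(g):
        return np.expand_dims(g, axis) * soft

    return t._unary(out_data, vjp)


def l2_normalize_rows(t: Tensor, eps: float = 1e-12) -> Tensor:
    """Normalise each row of a 2-D tensor to unit Euclidean norm."""
    norms = np.sqrt((t.data ** 2).sum(axis=1, keepdims=True)) + eps
    y = t.data / norms

    def vjp(g):
        return (g - y * (g * y).sum(axis=1, keepdims=True)) / norms

    return t._unary(y, vjp)


def conv2d(x: Tensor, w: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, square kernel, no bias.

    Implemented as im2col + one GEMM.  The padded input is first
    transposed to channel-first (C, B, H, W) so that the kh*kw shifted
    column blocks are near-contiguous slice copies; the column matrix is
    cached on the tape for the weight/input backward passes.
    """
    xd, wd = x.data, w.data
    B, C, H, W = xd.shape
    O, Ci, kh, kw = wd.shape
    if Ci != C:
        raise ValueError(f"conv2d: input has {C} channels, kernel expects {Ci}")
    s, p = stride, padding
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
    Ho = (xp.shape[2] - kh) // s + 1
    Wo = (xp.shape[3] - kw) // s + 1
    xt = np.ascontiguousarray(xp.transpose(1, 0, 2, 3))  # (C, B, Hp, Wp)
    cols4 = np.empty((C, kh * kw, B, Ho, Wo), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            cols4[:, i * kw + j] = xt[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
    cols = cols4.reshape(C * kh * kw, B * Ho * Wo)
    wmat = wd.reshape(O, C * kh * kw)
    out_data = np.ascontiguousarray(
        (wmat @ cols).reshape(O, B, Ho, Wo).transpose(1, 0, 2, 3))

    out = Tensor(out_data)
    if _grad_enabled and (x._needs_graph() or w._needs_graph()):
        out._parents = (x, w)

        def bwd(g):
            gm = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(
                O, B * Ho * Wo)
            if w._needs_graph():
                _accum(w, (gm @ cols.T).reshape(wd.shape))
            if x._needs_graph():
                dcols = (wmat.T @ gm).reshape(C, kh, kw, B, Ho, Wo)
                dxt = np.zeros_like(xt)
                for i in range(kh):
                    for j in range(kw):
                        dxt[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += \
                            dcols[:, i, j]
                dxp = dxt.transpose(1, 0, 2, 3)
                _accum(x, dxp[:, :, p:p + H, p:p + W] if p else dxp)

        out._backward = bwd
    return out


def dropout(t: Tensor, p: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not training or p == 0.0:
        return t
    mask = (rng.random(t.data.shape) >= p).astype(t.data.dtype) / (1.0 - p)
    return t * Tensor(mask)
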