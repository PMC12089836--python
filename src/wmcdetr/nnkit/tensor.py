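"""Minimal reverse-mode autodiff over numpy arrays.

Two execution modes share one code path:

* numeric — ``Tensor.data`` holds a float32/float64 ndarray and every op
  records a backward closure for reverse-mode differentiation;
* meta — ``Tensor.data is None`` and only shapes propagate.  Ops that are
  matrix-multiply shaped (matmul, conv) add their cost to a global FLOP
  counter under the 2 x multiply-accumulate convention; elementwise ops,
  normalisation, pooling and interpolation count zero, matching the
  convention used by common per-layer profilers.
"""

from __future__ import annotations

import numpy as np

# Global FLOP accumulator for meta-mode execution (see profiler).
_FLOPS = [0]


def reset_flops() -> None:
    _FLOPS[0] = 0


def get_flops() -> int:
    return _FLOPS[0]


def add_flops(n: int) -> None:
    _FLOPS[0] += int(n)


class Tensor:
    """An ndarray with an optional grad and a backward closure."""

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None,
                 shape=None):
        if data is None:
            self.data = None
            self._shape = tuple(int(s) for s in shape)
        else:
            if not isinstance(data, np.ndarray):
                data = np.asarray(data)
            if data.dtype not in (np.float32, np.float64):
                data = data.astype(np.float32)
            self.data = data
            self._shape = data.shape
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- basic introspection ------------------------------------------------
    @property
    def shape(self):
        return self._shape

    @property
    def ndim(self):
        return len(self._shape)

    @property
    def is_meta(self):
        return self.data is None

    def numel(self):
        n = 1
        for s in self._shape:
            n *= s
        return n

    def numpy(self):
        return self.data

    def item(self):
        return float(self.data)

    def detach(self):
        if self.is_meta:
            return meta(self._shape)
        return Tensor(self.data)

    def __repr__(self):
        if self.is_meta:
            return f"Tensor(meta, shape={self._shape})"
        return f"Tensor(shape={self._shape}, grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def backward(self, grad=None):
        if self.is_meta:
            raise RuntimeError("cannot backpropagate through a meta tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            if t._prev:
                # free interior grads eagerly; leaves keep theirs
                t.grad = None if t is not self else t.grad

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -ensure(other))

    def __rsub__(self, other):
        return add(ensure(other), -self)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, pow_(ensure(other), -1.0))

    def __rtruediv__(self, other):
        return mul(ensure(other), pow_(self, -1.0))

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # -- method sugar -------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)

    def exp(self):
        return exp(self)

    def __abs__(self):
        return abs_(self)

    def sqrt(self):
        return pow_(self, 0.5)


def ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def meta(shape) -> Tensor:
    return Tensor(None, shape=shape)


def _any_meta(*ts):
    return any(isinstance(t, Tensor) and t.is_meta for t in ts)


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == tuple(shape):
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _node(data, parents, backward):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req,
                  _prev=[p for p in parents if p.requires_grad] if req else (),
                  _backward=backward if req else None)


def _accum(t: Tensor, g):
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad += g


# -- elementwise ------------------------------------------------------------

def add(a, b):
    a, b = ensure(a), ensure(b)
    if _any_meta(a, b):
        return meta(np.broadcast_shapes(a.shape, b.shape))
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g, b.shape))

    return _node(out_data, (a, b), bw)


def mul(a, b):
    a = ensure(a)
    if isinstance(b, (int, float)):
        if a.is_meta:
            return meta(a.shape)
        c = float(b)

        def bws(g):
            _accum(a, g * c)

        return _node(a.data * c, (a,), bws)
    b = ensure(b)
    if _any_meta(a, b):
        return meta(np.broadcast_shapes(a.shape, b.shape))

    def bw(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * a.data, b.shape))

    return _node(a.data * b.data, (a, b), bw)


def pow_(a, p):
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)
    p = float(p)
    out = a.data ** p

    def bw(g):
        _accum(a, g * p * a.data ** (p - 1.0))

    return _node(out, (a,), bw)


def exp(a):
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)
    out = np.exp(a.data)

    def bw(g):
        _accum(a, g * out)

    return _node(out, (a,), bw)


def log(a):
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)

    def bw(g):
        _accum(a, g / a.data)

    return _node(np.log(a.data), (a,), bw)


def relu(a):
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)
    mask = a.data > 0

    def bw(g):
        _accum(a, g * mask)

    return _node(a.data * mask, (a,), bw)


def relu6(a):
    return clip(a, 0.0, 6.0)


def clip(a, lo, hi):
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)
    out = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def bw(g):
        _accum(a, g * mask)

    return _node(out, (a,), bw)


def abs_(a):
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)
    sign = np.sign(a.data)

    def bw(g):
        _accum(a, g * sign)

    return _node(np.abs(a.data), (a,), bw)


def sigmoid(a):
    from scipy.special import expit
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)
    out = expit(a.data)

    def bw(g):
        _accum(a, g * out * (1.0 - out))

    return _node(out, (a,), bw)


def silu(a):
    from scipy.special import expit
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)
    s = expit(a.data)
    out = a.data * s

    def bw(g):
        _accum(a, g * (s + a.data * s * (1.0 - s)))

    return _node(out, (a,), bw)


def hsigmoid(a):
    """Hard sigmoid clamp(t + 3, 0, 6) / 6."""
    return clip(add(a, 3.0), 0.0, 6.0) / 6.0


# -- shape manipulation ------------------------------------------------------

def reshape(a, shape):
    a = ensure(a)
    shape = tuple(shape)
    if a.is_meta:
        return meta(np.empty(a.shape, dtype=np.int8).reshape(shape).shape)
    old = a.data.shape
    out = a.data.reshape(shape)

    def bw(g):
        _accum(a, g.reshape(old))

    return _node(out, (a,), bw)


def transpose(a, axes):
    a = ensure(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    if a.is_meta:
        return meta(tuple(a.shape[i] for i in axes))
    out = np.transpose(a.data, axes)

    def bw(g):
        _accum(a, np.transpose(g, inv))

    return _node(out, (a,), bw)


def getitem(a, idx):
    a = ensure(a)
    if a.is_meta:
        return meta(np.empty(a.shape, dtype=np.int8)[idx].shape)
    out = a.data[idx]

    def bw(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        _accum(a, full)

    # basic slicing yields a view; safe because tensor data is never
    # mutated in place once created (optimizers touch only leaf params)
    return _node(out, (a,), bw)


def concat(ts, axis=0):
    ts = [ensure(t) for t in ts]
    if _any_meta(*ts):
        shp = list(ts[0].shape)
        shp[axis] = sum(t.shape[axis] for t in ts)
        return meta(tuple(shp))
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accum(t, g[tuple(sl)])

    return _node(out, ts, bw)


def pad2d(a, pad, value=0.0):
    """Pad the last two axes by ``pad = (top, bottom, left, right)``."""
    a = ensure(a)
    t, b, l, r = pad
    if a.is_meta:
        s = list(a.shape)
        s[-2] += t + b
        s[-1] += l + r
        return meta(tuple(s))
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    out = np.pad(a.data, width, constant_values=value)
    H, W = a.shape[-2], a.shape[-1]

    def bw(g):
        sl = (Ellipsis, slice(t, t + H), slice(l, l + W))
        _accum(a, g[sl])

    return _node(out, (a,), bw)


def reflect_pad2d(a, pad):
    a = ensure(a)
    t, b, l, r = pad
    if a.is_meta:
        s = list(a.shape)
        s[-2] += t + b
        s[-1] += l + r
        return meta(tuple(s))
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    out = np.pad(a.data, width, mode="reflect")
    H, W = a.shape[-2], a.shape[-1]

    def bw(g):
        gx = np.zeros_like(a.data)
        # fold reflected borders back; loop bounds are tiny (pad <= 1 here)
        idx_h = np.concatenate([np.arange(t, 0, -1), np.arange(H), np.arange(H - 2, H - 2 - b, -1)])
        idx_w = np.concatenate([np.arange(l, 0, -1), np.arange(W), np.arange(W - 2, W - 2 - r, -1)])
        np.add.at(gx, (Ellipsis, idx_h[:, None], idx_w[None, :]), g)
        _accum(a, gx)

    return _node(out, (a,), bw)


def replicate_pad2d(a, pad):
    """Edge-replication padding of the last two axes (constant-preserving)."""
    a = ensure(a)
    t, b, l, r = pad
    if a.is_meta:
        s = list(a.shape)
        s[-2] += t + b
        s[-1] += l + r
        return meta(tuple(s))
    width = [(0, 0)] * (a.ndim - 2) + [(t, b), (l, r)]
    out = np.pad(a.data, width, mode="edge")
    H, W = a.shape[-2], a.shape[-1]

    def bw(g):
        gx = np.zeros_like(a.data)
        idx_h = np.concatenate([np.zeros(t, int), np.arange(H), np.full(b, H - 1)])
        idx_w = np.concatenate([np.zeros(l, int), np.arange(W), np.full(r, W - 1)])
        np.add.at(gx, (Ellipsis, idx_h[:, None], idx_w[None, :]), g)
        _accum(a, gx)

    return _node(out, (a,), bw)


# -- reductions --------------------------------------------------------------

def sum_(a, axis=None, keepdims=False):
    a = ensure(a)
    if a.is_meta:
        return meta(np.empty(a.shape, dtype=np.int8).sum(axis=axis, keepdims=keepdims).shape)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            _accum(a, np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.shape).copy())

    return _node(out, (a,), bw)


def mean(a, axis=None, keepdims=False):
    a = ensure(a)
    if axis is None:
        n = a.numel()
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.shape[ax]
    return sum_(a, axis, keepdims) * (1.0 / n)


def softmax(a, axis=-1):
    a = ensure(a)
    if a.is_meta:
        return meta(a.shape)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        gs = (g * out).sum(axis=axis, keepdims=True)
        _accum(a, out * (g - gs))

    return _node(out, (a,), bw)


def logsumexp(a, axis=-1, keepdims=False):
    a = ensure(a)
    if a.is_meta:
        return meta(np.empty(a.shape, dtype=np.int8).sum(axis=axis, keepdims=keepdims).shape)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e.sum(axis=axis, keepdims=True)
    out = (np.log(s) + m) if keepdims else np.squeeze(np.log(s) + m, axis=axis)
    sm = e / s

    def bw(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, sm * g)

    return _node(out, (a,), bw)


# -- matmul ------------------------------------------------------------------

def matmul(a, b):
    a, b = ensure(a), ensure(b)
    if _any_meta(a, b):
        sa, sb = a.shape, b.shape
        out_shape = np.matmul(np.empty(sa, dtype=np.int8), np.empty(sb, dtype=np.int8)).shape
        batch = 1
        for s in out_shape[:-2]:
            batch *= s
        add_flops(2 * batch * out_shape[-2] * out_shape[-1] * sa[-1])
        return meta(out_shape)
    out = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            _accum(a, _unbroadcast(ga, a.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            _accum(b, _unbroadcast(gb, b.shape))

    return _node(out, (a, b), bw)
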