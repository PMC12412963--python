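"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A small tape-based engine providing exactly the operations a convolutional
detector needs: elementwise arithmetic, sigmoid/SiLU, conv2d (im2col backed
by BLAS matmul), max-pooling, nearest upsampling, batch normalization,
concatenation, reductions and (advanced) indexing.  Everything is float32.

Gradients are accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`,
which topologically sorts the tape.  Constants (python scalars / ndarrays)
participate in ops without being wrapped.
"""

from __future__ import annotations

import numpy as np

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling graph construction (inference / decoding)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _data(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self):
        return float(self.data)

    def numpy(self):
        return self.data

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- op construction helper -------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _GRAD_ENABLED and any(
            isinstance(p, Tensor) and (p.requires_grad or p._prev) for p in parents
        ):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if isinstance(p, Tensor))
            out._backward = backward
        return out

    @staticmethod
    def _accum(t, g):
        if not isinstance(t, Tensor):
            return
        g = _unbroadcast(g, t.data.shape)
        t.grad = g if t.grad is None else t.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        a, b = self, other
        out_data = a.data + _data(b)

        def bw(g):
            Tensor._accum(a, g)
            Tensor._accum(b, g)

        return Tensor._make(out_data, (a, b), bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, other
        bd = _data(b)
        out_data = a.data * bd

        def bw(g):
            Tensor._accum(a, g * bd)
            Tensor._accum(b, g * a.data)

        return Tensor._make(out_data, (a, b), bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-1.0 * _as_tensor_or_const(other))

    def __rsub__(self, other):
        return _as_tensor_or_const(other) + (-self)

    def __truediv__(self, other):
        a, b = self, other
        bd = _data(b)
        out_data = a.data / bd

        def bw(g):
            Tensor._accum(a, g / bd)
            Tensor._accum(b, -g * a.data / (bd * bd))

        return Tensor._make(out_data, (a, b), bw)

    def __rtruediv__(self, other):
        return _as_tensor_or_const(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data**p

        def bw(g):
            Tensor._accum(a, g * p * a.data ** (p - 1))

        return Tensor._make(out_data, (a,), bw)

    # -- elementwise functions --------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            Tensor._accum(a, g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self
        out_data = np.log(a.data)

        def bw(g):
            Tensor._accum(a, g / a.data)

        return Tensor._make(out_data, (a,), bw)

    def sqrt(self):
        return self**0.5

    def atan(self):
        a = self
        out_data = np.arctan(a.data)

        def bw(g):
            Tensor._accum(a, g / (1.0 + a.data * a.data))

        return Tensor._make(out_data, (a,), bw)

    def sigmoid(self):
        a = self
        out_data = _sigmoid(a.data)

        def bw(g):
            Tensor._accum(a, g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), bw)

    def silu(self):
        a = self
        s = _sigmoid(a.data)
        out_data = a.data * s

        def bw(g):
            Tensor._accum(a, g * (s * (1.0 + a.data * (1.0 - s))))

        return Tensor._make(out_data, (a,), bw)

    def logaddexp0(self):
        """log(1 + exp(x)), numerically stable (softplus)."""
        a = self
        out_data = np.logaddexp(0.0, a.data)

        def bw(g):
            Tensor._accum(a, g * _sigmoid(a.data))

        return Tensor._make(out_data, (a,), bw)

    def clamp(self, lo=None, hi=None):
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = np.ones_like(a.data)
        if lo is not None:
            mask *= a.data >= lo
        if hi is not None:
            mask *= a.data <= hi

        def bw(g):
            Tensor._accum(a, g * mask)

        return Tensor._make(out_data, (a,), bw)

    def maximum(self, other):
        a, b = self, other
        bd = _data(b)
        out_data = np.maximum(a.data, bd)
        amask = a.data >= bd

        def bw(g):
            Tensor._accum(a, g * amask)
            Tensor._accum(b, g * ~amask)

        return Tensor._make(out_data, (a, b), bw)

    def minimum(self, other):
        a, b = self, other
        bd = _data(b)
        out_data = np.minimum(a.data, bd)
        amask = a.data <= bd

        def bw(g):
            Tensor._accum(a, g * amask)
            Tensor._accum(b, g * ~amask)

        return Tensor._make(out_data, (a, b), bw)

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = a.data.reshape(shape)
        orig = a.data.shape

        def bw(g):
            Tensor._accum(a, g.reshape(orig))

        return Tensor._make(out_data, (a,), bw)

    def transpose(self, *axes):
        a = self
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        out_data = a.data.transpose(axes)
        inv = np.argsort(axes)

        def bw(g):
            Tensor._accum(a, g.transpose(inv))

        return Tensor._make(out_data, (a,), bw)

    def __getitem__(self, idx):
        a = self
        out_data = a.data[idx]
        basic = isinstance(idx, (int, slice)) or (
            isinstance(idx, tuple)
            and all(isinstance(i, (int, slice, type(Ellipsis), type(None))) for i in idx)
        )

        def bw(g):
            dx = np.zeros_like(a.data)
            if basic:
                dx[idx] += g
            else:
                np.add.at(dx, idx, g)
            Tensor._accum(a, dx)

        return Tensor._make(out_data, (a,), bw)

    def sum(self, axis=None, keepdims=False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                Tensor._accum(a, np.broadcast_to(g, a.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                Tensor._accum(a, np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(out_data, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[i] for i in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def _as_tensor_or_const(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def cat(tensors, axis=0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            Tensor._accum(t, piece)

    return Tensor._make(out_data, tuple(tensors), bw)


def stack(tensors, axis=0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            Tensor._accum(t, np.take(g, i, axis=axis))

    return Tensor._make(out_data, tuple(tensors), bw)


# ---------------------------------------------------------------------------
# spatial ops (NCHW)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution, im2col + matmul. x: (N,C,H,W); w: (O,C,kh,kw)."""
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, _, kh, kw = wd.shape
    s, p = stride, padding
    if p:
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)))
    else:
        xp = xd
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    if kh == 1 and kw == 1 and s == 1 and p == 0:
        cols = xd.reshape(N, C, H * W)
    else:
        cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=np.float32)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
        cols = cols.reshape(N, C * kh * kw, Ho * Wo)
    wmat = wd.reshape(O, C * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(N, O, Ho, Wo)
    if b is not None:
        out_data += b.data.reshape(1, O, 1, 1)

    def bw(g):
        gmat = g.reshape(N, O, Ho * Wo)
        dw = np.einsum("nop,ncp->oc", gmat, cols, optimize=True)
        Tensor._accum(w, dw.reshape(wd.shape))
        if b is not None:
            Tensor._accum(b, g.sum(axis=(0, 2, 3)))
        if isinstance(x, Tensor) and (x.requires_grad or x._prev):
            dcols = np.matmul(wmat.T, gmat)  # (N, Ckk, HoWo)
            if kh == 1 and kw == 1 and s == 1 and p == 0:
                Tensor._accum(x, dcols.reshape(N, C, H, W))
            else:
                dcols = dcols.reshape(N, C, kh, kw, Ho, Wo)
                dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=np.float32)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, i, j]
                Tensor._accum(x, dxp[:, :, p:p + H, p:p + W] if p else dxp)

    parents = (x, w, b) if b is not None else (x, w)
    return Tensor._make(out_data, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 stride-2 max pool (even spatial dims required)."""
    xd = x.data
    N, C, H, W = xd.shape
    assert H % 2 == 0 and W % 2 == 0, "maxpool2x2 requires even spatial dims"
    r = xd.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    r = r.reshape(N, C, H // 2, W // 2, 4)
    idx = r.argmax(axis=-1)
    out_data = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        dr = np.zeros((N, C, H // 2, W // 2, 4), dtype=np.float32)
        np.put_along_axis(dr, idx[..., None], g[..., None], axis=-1)
        dx = dr.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        Tensor._accum(x, dx.reshape(N, C, H, W))

    return Tensor._make(out_data, (x,), bw)


def maxpool_same(x: Tensor, k: int = 5) -> Tensor:
    """k x k stride-1 max pool with same padding (SPP-style)."""
    xd = x.data
    N, C, H, W = xd.shape
    p = k // 2
    xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    win = np.empty((N, C, k * k, H, W), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            win[:, :, i * k + j] = xp[:, :, i:i + H, j:j + W]
    idx = win.argmax(axis=2)
    out_data = np.take_along_axis(win, idx[:, :, None], axis=2)[:, :, 0]

    def bw(g):
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[:, :, None], g[:, :, None], axis=2)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + H, j:j + W] += dwin[:, :, i * k + j]
        Tensor._accum(x, dxp[:, :, p:p + H, p:p + W])

    return Tensor._make(out_data, (x,), bw)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    xd = x.data
    N, C, H, W = xd.shape
    out_data = xd.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        Tensor._accum(x, g.reshape(N, C, H, 2, W, 2).sum(axis=(3, 5)))

    return Tensor._make(out_data, (x,), bw)


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor,
              running_mean: np.ndarray, running_var: np.ndarray,
              training: bool, momentum: float = 0.03,
              eps: float = 1e-3) -> Tensor:
    """Batch normalization over (N,H,W) per channel; updates running stats."""
    xd = x.data
    N, C, H, W = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (N * H * W / max(N * H * W - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    out_data = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        Tensor._accum(beta, g.sum(axis=(0, 2, 3)))
        Tensor._accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if not (isinstance(x, Tensor) and (x.requires_grad or x._prev)):
            return
        gi = g * gamma.data.reshape(1, C, 1, 1)
        if training:
            m = N * H * W
            s1 = gi.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True)
            dx = (gi - s1 / m - xhat * s2 / m) * inv.reshape(1, C, 1, 1)
        else:
            dx = gi * inv.reshape(1, C, 1, 1)
        Tensor._accum(x, dx.astype(np.float32))

    return Tensor._make(out_data, (x, gamma, beta), bw)
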