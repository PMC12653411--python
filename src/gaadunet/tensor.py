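"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine provides exactly the operations the segmentation network needs:
broadcasting arithmetic, matmul (batched), reshape/permute/concat/narrow,
elementwise nonlinearities, stable softmax, reductions, 2-D convolution
(im2col, with dilation), 2×2 max pooling, and bilinear upsampling expressed
as interpolation-matrix products so both directions run through BLAS.

Gradients flow through a dynamically built tape; ``backward`` walks it in
reverse topological order. ``no_grad`` disables tape construction for
inference. All gradient rules are validated against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables gradient-tape construction."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _as_array(x, dtype=None):
    if isinstance(x, Tensor):
        raise TypeError("expected raw array, got Tensor")
    a = np.asarray(x)
    if a.dtype.kind != "f":
        a = a.astype(np.float32)
    if dtype is not None and a.dtype != dtype:
        a = a.astype(dtype)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ---- plumbing -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and not t._parents:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if pg is None:
                        continue
                    key = id(parent)
                    if key in grads:
                        grads[key] = grads[key] + pg
                    else:
                        grads[key] = pg

    # ---- helpers for op construction -----------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out._parents = ()
        out._backward = None
        if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        else:
            out.requires_grad = False
        return out

    @staticmethod
    def _coerce(x, like):
        if isinstance(x, Tensor):
            return x
        return Tensor(np.asarray(x, dtype=like.data.dtype))

    # ---- arithmetic -----------------------------------------------------

    def __add__(self, other):
        other = Tensor._coerce(other, self)
        a, b = self, other
        out = a.data + b.data
        return Tensor._make(out, (a, b), lambda g: (
            _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        other = Tensor._coerce(other, self)
        a, b = self, other
        return Tensor._make(a.data - b.data, (a, b), lambda g: (
            _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)))

    def __rsub__(self, other):
        return Tensor._coerce(other, self).__sub__(self)

    def __mul__(self, other):
        other = Tensor._coerce(other, self)
        a, b = self, other
        return Tensor._make(a.data * b.data, (a, b), lambda g: (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._coerce(other, self)
        a, b = self, other
        out = a.data / b.data
        return Tensor._make(out, (a, b), lambda g: (
            _unbroadcast(g / b.data, a.data.shape),
            _unbroadcast(-g * out / b.data, b.data.shape)))

    def __rtruediv__(self, other):
        return Tensor._coerce(other, self).__truediv__(self)

    def __pow__(self, p: float):
        a = self
        out = a.data ** p
        return Tensor._make(out, (a,), lambda g: (g * p * a.data ** (p - 1),))

    def sqrt(self):
        return self ** 0.5

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: (g * out,))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: (g / a.data,))

    # ---- nonlinearities -------------------------------------------------

    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: (g * mask,))

    def sigmoid(self):
        a = self
        out = 1.0 / (1.0 + np.exp(-a.data))
        return Tensor._make(out, (a,), lambda g: (g * out * (1.0 - out),))

    def softmax(self, axis: int = 1):
        a = self
        m = a.data.max(axis=axis, keepdims=True)
        e = np.exp(a.data - m)
        out = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            return (out * (g - dot),)

        return Tensor._make(out, (a,), backward)

    # ---- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.data.shape).copy(),)

        return Tensor._make(np.asarray(out), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ---- shape ops ------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: (g.reshape(old),))

    def permute(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: (g.transpose(inv),))

    def narrow(self, axis: int, start: int, length: int):
        a = self
        idx = [slice(None)] * a.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)

        def backward(g):
            ga = np.zeros_like(a.data)
            ga[idx] = g
            return (ga,)

        return Tensor._make(np.ascontiguousarray(a.data[idx]), (a,), backward)

    def __matmul__(self, other):
        other = Tensor._coerce(other, self)
        a, b = self, other
        out = a.data @ b.data

        def backward(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            return (_unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape))

        return Tensor._make(out, (a, b), backward)


# ---- structural ops ------------------------------------------------------


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def backward(g):
        return tuple(np.ascontiguousarray(piece) for piece in
                     np.split(g, np.cumsum(sizes)[:-1], axis=axis))

    return Tensor._make(out, tensors, backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation via im2col + batched GEMM.

    ``x``: (B, C, H, W); ``w``: (Cout, C, kh, kw); ``b``: (Cout,) or None.
    """
    B, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
    s, p, d = stride, padding, dilation
    Ho = (H + 2 * p - d * (kh - 1) - 1) // s + 1
    Wo = (W + 2 * p - d * (kw - 1) - 1) // s + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("conv2d output would be empty")
    L = Ho * Wo

    if kh == kw == 1 and s == 1 and p == 0:  # pointwise fast path
        x2 = x.data.reshape(B, C, L)
        w2 = w.data.reshape(Co, C)
        out = np.matmul(w2, x2)
        if b is not None:
            out = out + b.data.reshape(1, Co, 1)
        out = out.reshape(B, Co, Ho, Wo)

        def backward1x1(g):
            g2 = g.reshape(B, Co, L)
            gw = np.matmul(g2.transpose(1, 0, 2).reshape(Co, B * L),
                           x2.transpose(0, 2, 1).reshape(B * L, C))
            gx = np.matmul(w2.T, g2).reshape(B, C, H, W)
            if b is not None:
                return gx, gw.reshape(w.data.shape), g2.sum(axis=(0, 2))
            return gx, gw.reshape(w.data.shape)

        parents = (x, w) if b is None else (x, w, b)
        return Tensor._make(out, parents, backward1x1)

    if p:
        xp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
        xp[:, :, p: p + H, p: p + W] = x.data
    else:
        xp = x.data
    # window view (B, C, Ho', Wo', kh, kw) with dilation via step slicing
    win = np.lib.stride_tricks.sliding_window_view(
        xp, (1 + d * (kh - 1), 1 + d * (kw - 1)), axis=(2, 3))
    win = win[:, :, ::s, ::s, ::d, ::d]
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)
                                ).reshape(B, C * kh * kw, L)
    w2 = w.data.reshape(Co, C * kh * kw)
    out = np.matmul(w2, cols)  # (B, Co, L)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1)
    out = out.reshape(B, Co, Ho, Wo)

    def backward(g):
        g2 = g.reshape(B, Co, L)
        gw = np.matmul(g2.transpose(1, 0, 2).reshape(Co, B * L),
                       cols.transpose(0, 2, 1).reshape(B * L, C * kh * kw))
        gcols = np.matmul(w2.T, g2)  # (B, C*kh*kw, L)
        gcols = gcols.reshape(B, C, kh * kw, Ho, Wo)
        gxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=x.data.dtype)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i * d: i * d + (Ho - 1) * s + 1: s,
                    j * d: j * d + (Wo - 1) * s + 1: s] += gcols[:, :, i * kw + j]
        gx = gxp[:, :, p: p + H, p: p + W] if p else gxp
        gb = g2.sum(axis=(0, 2)) if b is not None else None
        if b is not None:
            return gx, gw.reshape(w.data.shape), gb
        return gx, gw.reshape(w.data.shape)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out, parents, backward)


def maxpool2d(x: Tensor) -> Tensor:
    """2×2 max pooling with stride 2 (spatial dims must be even)."""
    B, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2d requires even spatial dimensions")
    win = x.data.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(B, C, H // 2, W // 2, 4)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, arg[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(B, C, H, W),)

    return Tensor._make(np.ascontiguousarray(out), (x,), backward)


def batchnorm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                running_mean: np.ndarray | None = None,
                running_var: np.ndarray | None = None,
                eps: float = 1e-5) -> Tensor:
    """Fused per-channel normalization of (B, C, H, W).

    With ``running_mean``/``running_var`` given (evaluation mode) the map is
    an affine transform with constant statistics; otherwise batch statistics
    over (B, H, W) are used and differentiated through.
    """
    B, C, H, W = x.data.shape
    axes = (0, 2, 3)
    n = B * H * W
    training_stats = running_mean is None
    if training_stats:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
    else:
        mu, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(1, C, 1, 1)) * invstd.reshape(1, C, 1, 1)
    out = xhat * gamma.data.reshape(1, C, 1, 1) + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        dxhat = g * gamma.data.reshape(1, C, 1, 1)
        if training_stats:
            t1 = dxhat.sum(axis=axes).reshape(1, C, 1, 1)
            t2 = (dxhat * xhat).sum(axis=axes).reshape(1, C, 1, 1)
            gx = (dxhat - t1 / n - xhat * t2 / n) * invstd.reshape(1, C, 1, 1)
        else:
            gx = dxhat * invstd.reshape(1, C, 1, 1)
        return gx.astype(x.data.dtype), dgamma, dbeta

    return Tensor._make(out.astype(x.data.dtype), (x, gamma, beta), backward)


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(out_size: int, in_size: int) -> np.ndarray:
    """Dense (out, in) bilinear interpolation matrix, half-pixel centers."""
    key = (out_size, in_size)
    m = _INTERP_CACHE.get(key)
    if m is None:
        src = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
        i0 = np.floor(src).astype(np.int64)
        t = (src - i0).astype(np.float32)
        i0c = np.clip(i0, 0, in_size - 1)
        i1c = np.clip(i0 + 1, 0, in_size - 1)
        m = np.zeros((out_size, in_size), dtype=np.float32)
        np.add.at(m, (np.arange(out_size), i0c), 1.0 - t)
        np.add.at(m, (np.arange(out_size), i1c), t)
        _INTERP_CACHE[key] = m
    return m


def upsample_bilinear2d(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resize of (B, C, H, W) to spatial ``size`` (align_corners=False)."""
    B, C, H, W = x.data.shape
    Ho, Wo = size
    A = _interp_matrix(Ho, H).astype(x.data.dtype)
    Bm = _interp_matrix(Wo, W).astype(x.data.dtype)
    # rows: (B,C,H,W) -> (B,C,Ho,W); cols: -> (B,C,Ho,Wo)
    out = np.einsum("oh,bchw->bcow", A, x.data, optimize=True)
    out = np.einsum("pw,bchw->bchp", Bm, out, optimize=True)

    def backward(g):
        gx = np.einsum("pw,bchp->bchw", Bm, g, optimize=True)
        gx = np.einsum("oh,bcow->bchw", A, gx, optimize=True)
        return (gx,)

    return Tensor._make(out, (x,), backward)
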