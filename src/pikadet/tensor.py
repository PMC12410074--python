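"""Reverse-mode automatic differentiation on numpy arrays.

A small define-by-run engine in the micrograd style: every operation builds a
node holding its inputs and a closure that propagates the upstream gradient.
Arrays are float32 throughout (NCHW layout for feature maps).  The op set is
exactly what the detector needs — grouped/strided 2-D convolution via im2col,
batch normalization, max / sliding-mean / adaptive-average pooling, separable
bilinear and nearest resampling, elementwise algebra and the usual
activations — nothing more.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "maximum", "minimum", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


class no_grad:
    """Context manager that disables graph construction (inference mode)."""

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


def _as_f32(x):
    a = np.asarray(x, dtype=np.float32)
    return a


def _expit(x: np.ndarray) -> np.ndarray:
    # overflow-free logistic
    return (0.5 * (1.0 + np.tanh(0.5 * x))).astype(x.dtype, copy=False)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = _as_f32(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._prev = _prev if self.requires_grad or any(p.requires_grad for p in _prev) else ()
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    def _node(self, data, prev, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.name = ""
        req = _GRAD_ENABLED and any(p.requires_grad for p in prev)
        out.requires_grad = req
        out._prev = tuple(prev) if req else ()
        out._backward = backward if req else None
        return out

    # -- basic properties -----------------------------------------------------
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
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # -- autodiff -------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_f32(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free closure + graph refs once consumed
                if node is not self:
                    node._backward = None
                    node._prev = ()

    def _accum(self, g):
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or not g.flags.owndata else g
        else:
            self.grad = self.grad + g

    # -- elementwise algebra --------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._node(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._node(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / (other.data * other.data), other.data.shape))

        return self._node(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def __pow__(self, p: float):
        out_data = self.data ** p

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._node(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return self._node(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._node(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._node(np.log(self.data), (self,), backward)

    def abs(self):
        s = np.sign(self.data)

        def backward(g):
            self._accum(g * s)

        return self._node(np.abs(self.data), (self,), backward)

    def clamp(self, lo=None, hi=None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask *= (self.data >= lo)
        if hi is not None:
            mask *= (self.data <= hi)

        def backward(g):
            self._accum(g * mask)

        return self._node(out_data, (self,), backward)

    def atan(self):
        def backward(g):
            self._accum(g / (1.0 + self.data * self.data))

        return self._node(np.arctan(self.data), (self,), backward)

    # -- activations ----------------------------------------------------------
    def sigmoid(self):
        out_data = _expit(self.data)

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._node(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._node(self.data * mask, (self,), backward)

    def relu6(self):
        out_data = np.clip(self.data, 0.0, 6.0)
        mask = (self.data > 0) & (self.data < 6.0)

        def backward(g):
            self._accum(g * mask)

        return self._node(out_data, (self,), backward)

    def silu(self):
        s = _expit(self.data)
        out_data = self.data * s

        def backward(g):
            self._accum(g * s * (1.0 + self.data * (1.0 - s)))

        return self._node(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        e = np.exp(self.data - m)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            self._accum(out_data * (g - dot))

        return self._node(out_data, (self,), backward)

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).astype(np.float32))

        return self._node(np.asarray(out_data, dtype=np.float32), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            self._accum(g.reshape(old))

        return self._node(out_data, (self,), backward)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def backward(g):
            self._accum(np.ascontiguousarray(g.transpose(inv)))

        return self._node(np.ascontiguousarray(self.data.transpose(axes)), (self,), backward)

    def narrow(self, axis: int, start: int, length: int):
        """Contiguous slice along one axis (differentiable)."""
        idx = [slice(None)] * self.data.ndim
        idx[axis] = slice(start, start + length)
        idx = tuple(idx)
        out_data = np.ascontiguousarray(self.data[idx])

        def backward(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return self._node(out_data, (self,), backward)

    def take_cells(self, rows: np.ndarray, cols: np.ndarray):
        """Gather rows of a 2-D (R, C)-shaped tensor: out[k] = self[rows[k], cols[k]]...

        For a 3-D tensor (N, C, A) gathers out[k, :] = self[rows[k], :, cols[k]].
        """
        assert self.data.ndim == 3
        out_data = np.ascontiguousarray(self.data[rows, :, cols])  # (K, C)

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, (rows, slice(None), cols), g)
            self._accum(full)

        return self._node(out_data, (self,), backward)

    # -- convolution ----------------------------------------------------------
    def conv2d(self, w: "Tensor", b: "Tensor | None" = None, stride: int = 1,
               padding: int = 0, groups: int = 1):
        return _conv2d(self, w, b, stride, padding, groups)

    # -- pooling / resampling -------------------------------------------------
    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0):
        return _maxpool2d(self, kernel, stride, padding)

    def blur_mean(self, kernel: int):
        return _blur_mean(self, kernel)

    def adaptive_avg_pool(self, out_h: int, out_w: int):
        n, c, h, w = self.data.shape
        return _sep_linear(self, _adaptive_matrix(h, out_h), _adaptive_matrix(w, out_w))

    def resize_bilinear(self, out_h: int, out_w: int):
        n, c, h, w = self.data.shape
        return _sep_linear(self, _bilinear_matrix(h, out_h), _bilinear_matrix(w, out_w))

    def upsample_nearest(self, factor: int = 2):
        n, c, h, w = self.data.shape
        return _sep_linear(self, _nearest_matrix(h, h * factor), _nearest_matrix(w, w * factor))


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, bnd in zip(tensors, offs[:-1], offs[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, bnd)
            t._accum(np.ascontiguousarray(g[tuple(idx)]))

    ref = tensors[0]
    return ref._node(out_data, tuple(tensors), backward)


def maximum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    mask = a.data >= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(g * mask, a.data.shape))
        b._accum(_unbroadcast(g * (~mask), b.data.shape))

    return a._node(out_data, (a, b), backward)


def minimum(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    mask = a.data <= b.data
    out_data = np.where(mask, a.data, b.data)

    def backward(g):
        a._accum(_unbroadcast(g * mask, a.data.shape))
        b._accum(_unbroadcast(g * (~mask), b.data.shape))

    return a._node(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# convolution internals (im2col for dense, tap loop for depthwise)
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    n, c, _, _ = xp.shape
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for ki in range(kh):
        for kj in range(kw):
            cols[:, :, ki, kj] = xp[:, :, ki:ki + ho * stride:stride, kj:kj + wo * stride:stride]
    return cols


def _col2im(cols: np.ndarray, xp_shape, kh: int, kw: int, stride: int, ho: int, wo: int) -> np.ndarray:
    dxp = np.zeros(xp_shape, dtype=cols.dtype)
    for ki in range(kh):
        for kj in range(kw):
            dxp[:, :, ki:ki + ho * stride:stride, kj:kj + wo * stride:stride] += cols[:, :, ki, kj]
    return dxp


def _conv2d(x: Tensor, w: Tensor, b, stride: int, padding: int, groups: int) -> Tensor:
    n, cin, h, wdt = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d channel mismatch: input has {cin} channels, weight expects "
            f"{cin_g * groups} (={cin_g} x {groups} groups)")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wdt + 2 * padding - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d output would be empty")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding))) \
        if padding else x.data

    from . import profiling as _prof
    if _prof._ACTIVE is not None:
        _prof._record_conv(cin, cout, kh * kw, groups, ho, wo, n)

    if groups == 1:
        cols = _im2col(xp, kh, kw, stride, ho, wo)              # (N,C,kh,kw,Ho,Wo)
        cols2 = cols.reshape(n, cin * kh * kw, ho * wo)
        wmat = w.data.reshape(cout, cin * kh * kw)
        out = np.einsum("ok,nkp->nop", wmat, cols2, optimize=True)
        out = out.reshape(n, cout, ho, wo)

        def backward(g):
            gmat = g.reshape(n, cout, ho * wo)
            if w.requires_grad:
                dw = np.einsum("nop,nkp->ok", gmat, cols2, optimize=True)
                w._accum(dw.reshape(w.data.shape))
            if x.requires_grad:
                dcols = np.einsum("ok,nop->nkp", wmat, gmat, optimize=True)
                dcols = dcols.reshape(n, cin, kh, kw, ho, wo)
                dxp = _col2im(dcols, xp.shape, kh, kw, stride, ho, wo)
                x._accum(dxp[:, :, padding:padding + h, padding:padding + wdt]
                         if padding else dxp)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))

    elif groups == cin and cout == cin and cin_g == 1:
        # depthwise: accumulate the kh*kw taps
        out = np.zeros((n, cin, ho, wo), dtype=np.float32)
        for ki in range(kh):
            for kj in range(kw):
                out += xp[:, :, ki:ki + ho * stride:stride, kj:kj + wo * stride:stride] \
                    * w.data[:, 0, ki, kj][None, :, None, None]

        def backward(g):
            if w.requires_grad:
                dw = np.zeros_like(w.data)
                for ki in range(kh):
                    for kj in range(kw):
                        patch = xp[:, :, ki:ki + ho * stride:stride, kj:kj + wo * stride:stride]
                        dw[:, 0, ki, kj] = (g * patch).sum(axis=(0, 2, 3))
                w._accum(dw)
            if x.requires_grad:
                dxp = np.zeros_like(xp)
                for ki in range(kh):
                    for kj in range(kw):
                        dxp[:, :, ki:ki + ho * stride:stride, kj:kj + wo * stride:stride] += \
                            g * w.data[:, 0, ki, kj][None, :, None, None]
                x._accum(dxp[:, :, padding:padding + h, padding:padding + wdt]
                         if padding else dxp)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2, 3)))

    else:
        raise NotImplementedError("only dense (groups=1) and depthwise convolutions supported")

    if b is not None:
        out = out + b.data[None, :, None, None]
    prev = (x, w) if b is None else (x, w, b)
    return x._node(out, prev, backward)


def _maxpool2d(x: Tensor, kernel: int, stride: int, padding: int) -> Tensor:
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=-np.inf) if padding else x.data
    ho = (h + 2 * padding - kernel) // stride + 1
    wo = (w + 2 * padding - kernel) // stride + 1
    cols = _im2col(xp, kernel, kernel, stride, ho, wo)          # (N,C,k,k,Ho,Wo)
    flat = cols.reshape(n, c, kernel * kernel, ho, wo)
    arg = flat.argmax(axis=2)
    out = np.take_along_axis(flat, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, arg[:, :, None], g[:, :, None], axis=2)
        dcols = dflat.reshape(n, c, kernel, kernel, ho, wo)
        dxp = _col2im(dcols, xp.shape, kernel, kernel, stride, ho, wo)
        x._accum(dxp[:, :, padding:padding + h, padding:padding + w] if padding else dxp)

    return x._node(out, (x,), backward)


def _box_sum(a: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window sum over the trailing two axes, window k x k centred,
    truncated at the borders (no padding contribution)."""
    r = k // 2
    h, w = a.shape[-2:]
    ch = np.concatenate([np.zeros((*a.shape[:-2], 1, w), a.dtype), a.cumsum(axis=-2)], axis=-2)
    hi = np.minimum(np.arange(h) + r + 1, h)
    lo = np.maximum(np.arange(h) - r, 0)
    rows = ch[..., hi, :] - ch[..., lo, :]
    cw = np.concatenate([np.zeros((*rows.shape[:-1], 1), a.dtype), rows.cumsum(axis=-1)], axis=-1)
    hj = np.minimum(np.arange(w) + r + 1, w)
    lj = np.maximum(np.arange(w) - r, 0)
    return cw[..., hj] - cw[..., lj]


def _box_count(h: int, w: int, k: int) -> np.ndarray:
    r = k // 2
    ch = (np.minimum(np.arange(h) + r + 1, h) - np.maximum(np.arange(h) - r, 0))
    cw = (np.minimum(np.arange(w) + r + 1, w) - np.maximum(np.arange(w) - r, 0))
    return (ch[:, None] * cw[None, :]).astype(np.float32)


def _blur_mean(x: Tensor, kernel: int) -> Tensor:
    """Size-preserving sliding mean that averages only in-bounds samples,
    so spatially constant inputs are reproduced exactly."""
    if kernel % 2 == 0:
        raise ValueError("blur kernel must be odd")
    h, w = x.data.shape[-2:]
    cnt = _box_count(h, w, kernel).astype(np.float64)
    # float64 running sums keep the in-window mean of a constant field
    # bit-exact (k*c and k*c/k are exactly representable)
    out = _box_sum(x.data.astype(np.float64), kernel) / cnt

    def backward(g):
        x._accum(_box_sum(g.astype(np.float64) / cnt, kernel).astype(np.float32))

    return x._node(out.astype(np.float32), (x,), backward)


# -- separable linear resampling (adaptive pool / bilinear / nearest) --------

def _sep_linear(x: Tensor, rmat: np.ndarray, cmat: np.ndarray) -> Tensor:
    out = np.einsum("oh,nchw,pw->ncop", rmat, x.data, cmat, optimize=True)

    def backward(g):
        x._accum(np.einsum("oh,ncop,pw->nchw", rmat, g, cmat, optimize=True).astype(np.float32))

    return x._node(out.astype(np.float32), (x,), backward)


def _adaptive_matrix(n_in: int, n_out: int) -> np.ndarray:
    m = np.zeros((n_out, n_in), dtype=np.float32)
    for i in range(n_out):
        a = (i * n_in) // n_out
        b = -((-(i + 1) * n_in) // n_out)  # ceil
        m[i, a:b] = 1.0 / (b - a)
    return m


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Half-pixel-centre (align_corners=False) interpolation weights."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    f = (src - i0).astype(np.float32)
    for i in range(n_out):
        m[i, i0[i]] += 1.0 - f[i]
        m[i, i1[i]] += f[i]
    return m


def _nearest_matrix(n_in: int, n_out: int) -> np.ndarray:
    m = np.zeros((n_out, n_in), dtype=np.float32)
    idx = (np.arange(n_out) * n_in // n_out).clip(0, n_in - 1)
    m[np.arange(n_out), idx] = 1.0
    return m
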