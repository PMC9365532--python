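"""Reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` runs the chain rule over the recorded graph in
reverse topological order.  The operation set is exactly what the
segmentation network needs: broadcast arithmetic, 2-D convolution and
transposed convolution (NHWC layout, 3x3 "same" geometry), max/average
pooling, bilinear resizing, channel concatenation, pointwise nonlinearities,
reductions, dropout and a numerically stable binary cross-entropy on logits.

Layout convention: feature maps are rank-4 ``(batch, height, width,
channels)`` arrays; convolution kernels are ``(kh, kw, c_in, c_out)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "div",
    "neg",
    "power",
    "exp",
    "log",
    "leaky_relu",
    "sigmoid",
    "tanh",
    "concat",
    "reshape",
    "tsum",
    "tmean",
    "matmul",
    "conv2d",
    "conv_transpose2d",
    "max_pool2",
    "avg_pool2",
    "bilinear_resize",
    "dropout",
    "bce_with_logits",
]


class Tensor:
    """A node in the autodiff graph.

    Parameters
    ----------
    data:
        Array (or scalar) value of the node.
    requires_grad:
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- bookkeeping ------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.array(g)
        else:
            self.grad = self.grad + g

    def backward(self, grad=None) -> None:
        """Backpropagate from this node (defaults to d(self)/d(self)=1)."""
        if grad is None:
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
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(as_tensor(other)))

    def __rsub__(self, other):
        return add(as_tensor(other), neg(self))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(as_tensor(other), self)

    def __pow__(self, k):
        return power(self, k)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# -- arithmetic ----------------------------------------------------------


def _coerce_pair(a, b):
    """Wrap operands, keeping Python scalars at the tensor operand's dtype
    so float32 graphs are not silently promoted to float64."""
    if isinstance(a, Tensor) and not isinstance(b, Tensor) and np.isscalar(b):
        b = Tensor(np.asarray(b, dtype=a.data.dtype))
    elif isinstance(b, Tensor) and not isinstance(a, Tensor) and np.isscalar(a):
        a = Tensor(np.asarray(a, dtype=b.data.dtype))
    return as_tensor(a), as_tensor(b)


def add(a, b) -> Tensor:
    a, b = _coerce_pair(a, b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _coerce_pair(a, b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return _make(out_data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _coerce_pair(a, b)
    out_data = a.data / b.data

    def backward(g):
        a._accumulate(_unbroadcast(g / b.data, a.shape))
        b._accumulate(_unbroadcast(-g * a.data / (b.data**2), b.shape))

    return _make(out_data, (a, b), backward)


def neg(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(-g)

    return _make(-a.data, (a,), backward)


def power(a, k: float) -> Tensor:
    a = as_tensor(a)
    out_data = a.data**k

    def backward(g):
        a._accumulate(g * k * a.data ** (k - 1))

    return _make(out_data, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return _make(out_data, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(np.log(a.data), (a,), backward)


# -- nonlinearities ------------------------------------------------------


def leaky_relu(a, negative_slope: float = 0.01) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out_data = np.where(pos, a.data, negative_slope * a.data)

    def backward(g):
        a._accumulate(np.where(pos, g, g * negative_slope))

    return _make(out_data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # Stable piecewise evaluation.
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.clip(x, 0, None))),
                        np.exp(np.clip(x, None, 0)) / (1.0 + np.exp(np.clip(x, None, 0))))

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def tanh(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - out_data**2))

    return _make(out_data, (a,), backward)


# -- shape ops -----------------------------------------------------------


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return _make(out_data, tuple(tensors), backward)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    old = a.shape

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(a.data.reshape(shape), (a,), backward)


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_ % a.ndim for a_ in axes):
                g = np.expand_dims(g, ax)
        a._accumulate(np.broadcast_to(g, a.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(out_data, (a, b), backward)


# -- convolution ---------------------------------------------------------


def _zero_pad(x: np.ndarray, ph: int, pw: int) -> np.ndarray:
    """Zero-pad H and W of an NHWC array (faster than ``np.pad``)."""
    if ph == 0 and pw == 0:
        return x
    n, h, w, c = x.shape
    xp = np.zeros((n, h + 2 * ph, w + 2 * pw, c), dtype=x.dtype)
    xp[:, ph : ph + h, pw : pw + w, :] = x
    return xp


def _im2col(xp: np.ndarray, kh: int, kw: int, oh: int, ow: int,
            stride: int) -> np.ndarray:
    """Gather sliding 2-D windows into ``(n*oh*ow, kh*kw*ci)`` columns."""
    n, _, _, ci = xp.shape
    cols = np.empty((n, oh, ow, kh * kw * ci), dtype=xp.dtype)
    for u in range(kh):
        for v in range(kw):
            j = (u * kw + v) * ci
            cols[..., j : j + ci] = xp[:, u : u + stride * (oh - 1) + 1 : stride,
                                       v : v + stride * (ow - 1) + 1 : stride, :]
    return cols.reshape(n * oh * ow, kh * kw * ci)


def conv2d(x, w, b=None, stride: int = 1) -> Tensor:
    """2-D convolution, NHWC input, ``(kh, kw, c_in, c_out)`` kernel.

    Padding is symmetric ``(k-1)//2`` per side, so stride 1 preserves the
    spatial size and stride 2 yields ``ceil(H/2)`` (odd kernel sizes only).
    Implemented as a single GEMM over im2col columns; the columns are
    rebuilt in the backward pass rather than stored.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    n, h, wd, ci = x.shape
    kh, kw, ci_w, co = w.shape
    if ci != ci_w:
        raise ValueError(f"channel mismatch: input has {ci}, kernel expects {ci_w}")
    parents = (x, w) if b is None else (x, w, b)

    if kh == kw == 1 and stride == 1:
        # pointwise convolution: a plain GEMM over flattened pixels
        w2 = w.data.reshape(ci, co)
        x2 = x.data.reshape(n * h * wd, ci)
        out_data = (x2 @ w2).reshape(n, h, wd, co)
        if b is not None:
            out_data += b.data

        def backward_1x1(g):
            g2 = g.reshape(n * h * wd, co)
            w._accumulate((x2.T @ g2).reshape(w.shape))
            x._accumulate((g2 @ w2.T).reshape(x.shape))
            if b is not None:
                b._accumulate(_unbroadcast(g, b.shape))

        return _make(out_data, parents, backward_1x1)

    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    oh = (h + 2 * ph - kh) // stride + 1
    ow = (wd + 2 * pw - kw) // stride + 1
    xp = _zero_pad(x.data, ph, pw)
    w2 = w.data.reshape(kh * kw * ci, co)
    cols = _im2col(xp, kh, kw, oh, ow, stride)
    out_data = (cols @ w2).reshape(n, oh, ow, co)
    if b is not None:
        out_data += b.data

    def backward(g):
        g2 = g.reshape(n * oh * ow, co)
        # rebuild columns rather than retaining them: cheaper than holding
        # O(k^2) copies of every activation for the graph's lifetime
        cols_b = _im2col(xp, kh, kw, oh, ow, stride)
        w._accumulate((cols_b.T @ g2).reshape(w.shape))
        dcols = (g2 @ w2.T).reshape(n, oh, ow, kh * kw * ci)
        dxp = np.zeros(xp.shape, dtype=dcols.dtype)
        for u in range(kh):
            for v in range(kw):
                j = (u * kw + v) * ci
                dxp[:, u : u + stride * (oh - 1) + 1 : stride,
                    v : v + stride * (ow - 1) + 1 : stride, :] += \
                    dcols[..., j : j + ci]
        x._accumulate(dxp[:, ph : ph + h, pw : pw + wd, :])
        if b is not None:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, parents, backward)


def conv_transpose2d(x, w, b=None) -> Tensor:
    """Stride-2 transposed convolution that exactly doubles H and W.

    Geometry matches a 3x3 (odd) kernel with padding ``(k-1)//2`` and output
    padding 1, so it is the exact spatial inverse of ``conv2d(stride=2)`` on
    even-sized inputs.
    """
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    n, h, wd, ci = x.shape
    kh, kw, ci_w, co = w.shape
    if ci != ci_w:
        raise ValueError(f"channel mismatch: input has {ci}, kernel expects {ci_w}")
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    oh, ow = 2 * h, 2 * wd
    full_h, full_w = (h - 1) * 2 + kh, (wd - 1) * 2 + kw
    # one GEMM produces every kernel tap's contribution, then scatter-add
    wt = w.data.transpose(2, 0, 1, 3).reshape(ci, kh * kw * co)
    contrib = (x.data.reshape(n * h * wd, ci) @ wt).reshape(n, h, wd, kh, kw, co)
    tmp = np.zeros((n, full_h, full_w, co), dtype=contrib.dtype)
    for u in range(kh):
        for v in range(kw):
            tmp[:, u : u + 2 * (h - 1) + 1 : 2,
                v : v + 2 * (wd - 1) + 1 : 2, :] += contrib[:, :, :, u, v, :]
    out_data = tmp[:, ph : ph + oh, pw : pw + ow, :]
    if b is not None:
        out_data = out_data + b.data

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g = np.asarray(g)
        gt = np.zeros((n, full_h, full_w, co), dtype=g.dtype)
        gt[:, ph : ph + oh, pw : pw + ow, :] = g
        gcols = np.empty((n, h, wd, kh * kw * co), dtype=g.dtype)
        for u in range(kh):
            for v in range(kw):
                j = (u * kw + v) * co
                gcols[..., j : j + co] = gt[:, u : u + 2 * (h - 1) + 1 : 2,
                                            v : v + 2 * (wd - 1) + 1 : 2, :]
        g2 = gcols.reshape(n * h * wd, kh * kw * co)
        x2 = x.data.reshape(n * h * wd, ci)
        x._accumulate((g2 @ wt.T).reshape(x.shape))
        dw = (x2.T @ g2).reshape(ci, kh, kw, co).transpose(1, 2, 0, 3)
        w._accumulate(dw)
        if b is not None:
            b._accumulate(_unbroadcast(g, b.shape))

    return _make(out_data, parents, backward)


# -- pooling / resampling ------------------------------------------------


def max_pool2(x) -> Tensor:
    """2x2 max pooling with stride 2; odd sizes are padded with -inf."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    ph, pw = h % 2, w % 2
    xp = x.data
    if ph or pw:
        xp = np.pad(xp, ((0, 0), (0, ph), (0, pw), (0, 0)),
                    constant_values=-np.inf)
    oh, ow = xp.shape[1] // 2, xp.shape[2] // 2
    r = xp.reshape(n, oh, 2, ow, 2, c)
    out_data = r.max(axis=(2, 4))
    mask = r == out_data[:, :, None, :, None, :]
    # split gradient evenly across ties so finite-difference checks agree
    mask = (mask / mask.sum(axis=(2, 4), keepdims=True)).astype(out_data.dtype)

    def backward(g):
        gr = mask * g[:, :, None, :, None, :]
        gp = gr.reshape(n, oh * 2, ow * 2, c)
        x._accumulate(gp[:, :h, :w, :])

    return _make(out_data, (x,), backward)


def avg_pool2(x) -> Tensor:
    """2x2 average pooling with stride 2 (even spatial sizes only)."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 requires even spatial dims, got {h}x{w}")
    oh, ow = h // 2, w // 2
    out_data = x.data.reshape(n, oh, 2, ow, 2, c).mean(axis=(2, 4))

    def backward(g):
        gr = np.broadcast_to(g[:, :, None, :, None, :] / 4.0,
                             (n, oh, 2, ow, 2, c))
        x._accumulate(gr.reshape(n, h, w, c).copy())

    return _make(out_data, (x,), backward)


def _resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    pos = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    pos = np.clip(pos, 0, n_in - 1)
    i0 = np.floor(pos).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = pos - i0
    for o in range(n_out):
        a[o, i0[o]] += 1.0 - frac[o]
        a[o, i1[o]] += frac[o]
    return a


def bilinear_resize(x, out_hw) -> Tensor:
    """Bilinear resampling of an NHWC tensor to ``out_hw = (OH, OW)``."""
    x = as_tensor(x)
    n, h, w, c = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        def backward_id(g):
            x._accumulate(g)
        return _make(x.data.copy(), (x,), backward_id)
    ah = _resize_matrix(oh, h).astype(x.data.dtype)
    aw = _resize_matrix(ow, w).astype(x.data.dtype)
    # y[n,o,p,c] = sum_{h,w} ah[o,h] aw[p,w] x[n,h,w,c]
    t = np.tensordot(ah, x.data, axes=(1, 1))        # (OH, N, W, C)
    y = np.tensordot(aw, t, axes=(1, 2))             # (OW, OH, N, C)
    out_data = y.transpose(2, 1, 0, 3)

    def backward(g):
        t2 = np.tensordot(ah.T, g, axes=(1, 1))      # (H, N, OW, C)
        d = np.tensordot(aw.T, t2, axes=(1, 2))      # (W, H, N, C)
        x._accumulate(d.transpose(2, 1, 0, 3))

    return _make(out_data, (x,), backward)


def dropout(x, p: float, rng: np.random.Generator, training: bool = True) -> Tensor:
    """Inverted dropout; identity when not training or ``p == 0``."""
    x = as_tensor(x)
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)

    def backward(g):
        x._accumulate(g * keep)

    return _make(x.data * keep, (x,), backward)


def bce_with_logits(logits, targets) -> Tensor:
    """Elementwise binary cross-entropy on logits, numerically stable.

    ``targets`` is treated as a constant (no gradient) and follows the
    logits' dtype.
    """
    logits = as_tensor(logits)
    t = np.asarray(targets.data if isinstance(targets, Tensor) else targets,
                   dtype=logits.data.dtype)
    z = logits.data
    out_data = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-np.clip(z, 0, None))),
                 np.exp(np.clip(z, None, 0)) / (1.0 + np.exp(np.clip(z, None, 0))))

    def backward(g):
        logits._accumulate(g * (s - t))

    return _make(out_data, (logits,), backward)
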