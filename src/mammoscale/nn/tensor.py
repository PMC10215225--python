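"""Reverse-mode autodiff on numpy arrays.

A small define-by-run engine: each op returns a new :class:`Tensor` holding
a closure that propagates gradients to its parents. Only the operations
needed by the convolutional classifiers in this package are implemented,
all in float32, NCHW layout for image tensors.
"""

from __future__ import annotations

import contextlib

import numpy as np

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self, grad=None):
        """Backpropagate from this tensor through the recorded graph.

        Gradients accumulate on every tensor in the graph that either
        requires grad itself or lies on a path to one that does; this makes
        intermediate activations (e.g. the last feature map, for grad-CAM)
        inspectable after the call.
        """
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- convenience arithmetic -------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul_scalar(self, other)

    __rmul__ = __mul__


def _result(data, parents, backward):
    """Create an op result, recording the graph only when needed."""
    track = grad_enabled() and any(
        p.requires_grad or p._parents for p in parents
    )
    out = Tensor(data, requires_grad=track)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=False)
    else:
        t.grad = t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# -- elementwise / linear algebra -----------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    return _result(out_data, (a, b), backward)


def mul_scalar(a: Tensor, s: float) -> Tensor:
    s = float(s)

    def backward(g):
        _accum(a, g * s)

    return _result(a.data * s, (a,), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    return _result(out_data, (a, b), backward)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0

    def backward(g):
        _accum(a, g * mask)

    return _result(a.data * mask, (a,), backward)


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    return _result(s, (a,), backward)


def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape

    def backward(g):
        _accum(a, g.reshape(old))

    return _result(a.data.reshape(shape), (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = list(tensors)
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _result(out_data, tuple(tensors), backward)


def mean(a: Tensor) -> Tensor:
    n = a.data.size

    def backward(g):
        _accum(a, np.full_like(a.data, g / n))

    return _result(a.data.mean(), (a,), backward)


# -- conv / pool machinery --------------------------------------------------

def _im2col(x: np.ndarray, kh, kw, sh, sw, ph, pw):
    n, c, h, w = x.shape
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]
    ho, wo = win.shape[2], win.shape[3]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    return cols, ho, wo


def _col2im(dcols, xshape, kh, kw, sh, sw, ph, pw, ho, wo):
    n, c, h, w = xshape
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=np.float32)
    d = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += d[:, :, i, j]
    if ph or pw:
        return dxp[:, :, ph : ph + h, pw : pw + w]
    return dxp


def conv2d(x: Tensor, weight: Tensor, stride=1, padding=0) -> Tensor:
    """2D convolution (cross-correlation), bias-free; NCHW in, NCHW out."""
    sh = sw = int(stride)
    ph = pw = int(padding)
    cout, cin, kh, kw = weight.data.shape
    n = x.data.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, sh, sw, ph, pw)
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out = (cols @ wmat.T).reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    xshape = x.data.shape
    keep_cols = grad_enabled() and (x.requires_grad or x._parents or weight.requires_grad)
    cols_saved = cols if keep_cols else None

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
        _accum(weight, (gmat.T @ cols_saved).reshape(weight.data.shape))
        dcols = gmat @ wmat
        _accum(x, _col2im(dcols, xshape, kh, kw, sh, sw, ph, pw, ho, wo))

    return _result(np.ascontiguousarray(out), (x, weight), backward)


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    k = int(kernel)
    s = int(stride or kernel)
    p = int(padding)
    n, c, h, w = x.data.shape
    xp = x.data
    if p:
        xp = np.pad(xp, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        dflat = np.zeros((n, c, ho, wo, k * k), dtype=np.float32)
        np.put_along_axis(dflat, arg[..., None], g[..., None], axis=-1)
        dcols = np.ascontiguousarray(
            dflat.reshape(n, c, ho, wo, k, k).transpose(0, 2, 3, 1, 4, 5)
        ).reshape(n * ho * wo, c * k * k)
        _accum(x, _col2im(dcols, (n, c, h, w), k, k, s, s, p, p, ho, wo))

    return _result(np.ascontiguousarray(out), (x,), backward)


def avg_pool2d(x: Tensor, kernel: int, stride: int | None = None) -> Tensor:
    k = int(kernel)
    s = int(stride or kernel)
    n, c, h, w = x.data.shape
    win = np.lib.stride_tricks.sliding_window_view(x.data, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    out = win.mean(axis=(-2, -1))

    def backward(g):
        dcols = np.repeat(
            (g / (k * k)).transpose(0, 2, 3, 1).reshape(n * ho * wo, c, 1), k * k, axis=2
        ).reshape(n * ho * wo, c * k * k)
        _accum(x, _col2im(dcols, (n, c, h, w), k, k, s, s, 0, 0, ho, wo))

    return _result(np.ascontiguousarray(out), (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """NCHW -> NC mean over the spatial dimensions."""
    n, c, h, w = x.data.shape
    out = x.data.mean(axis=(2, 3))

    def backward(g):
        _accum(x, np.broadcast_to(g[:, :, None, None] / (h * w), (n, c, h, w)).astype(np.float32))

    return _result(out, (x,), backward)


def upsample_nearest(x: Tensor, size) -> Tensor:
    """Nearest-neighbour resize of an NCHW tensor to spatial `size`."""
    n, c, h, w = x.data.shape
    th, tw = size
    ri = (np.arange(th) * h) // th
    ci = (np.arange(tw) * w) // tw
    out = x.data[:, :, ri][:, :, :, ci]

    def backward(g):
        tmp = np.zeros((n, c, h, tw), dtype=np.float32)
        np.add.at(tmp, (slice(None), slice(None), ri), g)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        np.add.at(dx, (slice(None), slice(None), slice(None), ci), tmp)
        _accum(x, dx)

    return _result(out, (x,), backward)


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    n, c, h, w = x.data.shape
    if training:
        m = x.data.mean(axis=(0, 2, 3))
        v = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * m
        running_var *= 1 - momentum
        running_var += momentum * v * (n * h * w) / max(n * h * w - 1, 1)
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, g.sum(axis=(0, 2, 3)))
        gi = gamma.data[None, :, None, None] * inv[None, :, None, None]
        if training:
            cnt = n * h * w
            gm = g.mean(axis=(0, 2, 3), keepdims=True)
            gxm = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
            _accum(x, gi * (g - gm.reshape(1, c, 1, 1) - xhat * gxm.reshape(1, c, 1, 1)))
            del cnt
        else:
            _accum(x, gi * g)

    return _result(out, (x, gamma, beta), backward)


def linear(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """x (N,F) @ weight.T (F,C) + bias."""
    out = x.data @ weight.data.T
    if bias is not None:
        out = out + bias.data

    def backward(g):
        _accum(weight, g.T @ x.data)
        if bias is not None:
            _accum(bias, g.sum(axis=0))
        _accum(x, g @ weight.data)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _result(out, parents, backward)


# -- losses -----------------------------------------------------------------

def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; `labels` are integer class indices."""
    n = logits.data.shape[0]
    p = softmax(logits.data, axis=1)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()

    def backward(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        _accum(logits, g * grad / n)

    return _result(loss, (logits,), backward)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on a vector of logits."""
    z = logits.data.reshape(-1)
    t = np.asarray(targets, dtype=np.float32).reshape(-1)
    # log(1+exp(-|z|)) formulation for stability
    loss = (np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))).mean()
    s = 1.0 / (1.0 + np.exp(-z))
    n = z.size

    def backward(g):
        _accum(logits, (g * (s - t) / n).reshape(logits.data.shape))

    return _result(loss, (logits,), backward)
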