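"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery to express convolutional encoder-decoder networks:
tensors form a DAG of operations, and :meth:`Tensor.backward` runs the
chain rule in reverse topological order.  All arrays are float32 and the
engine is single-threaded and deterministic, which is what makes the
bit-reproducible training contract testable.  Gradients of every op are
checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add", "mul", "neg", "sub", "pow_const", "absolute",
    "relu", "sigmoid", "mean_all", "sum_all", "mean_axes", "concat",
    "conv2d", "maxpool2d", "avgpool2d", "resize_bilinear", "batchnorm",
    "l1_loss", "bce_loss",
]

_F = np.float32


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "parents", "backward_fn", "requires_grad")

    def __init__(self, data, parents=(), backward_fn=None, requires_grad=False):
        self.data = np.asarray(data, dtype=_F)
        self.parents = tuple(parents)
        self.backward_fn = backward_fn
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in self.parents)
        self.grad = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from this (scalar or any-shape) tensor, seeding with ones."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node.backward_fn is None or node.grad is None:
                continue
            grads = node.backward_fn(node.grad)
            for parent, g in zip(node.parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data
    return Tensor(out, (a, b), lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)))


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data
    return Tensor(
        out, (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, (a,), lambda g: (-g,))


def sub(a: Tensor, b: Tensor) -> Tensor:
    return add(a, neg(b))


def pow_const(a: Tensor, p: float) -> Tensor:
    out = a.data**p
    return Tensor(out, (a,), lambda g: (g * p * a.data ** (p - 1),))


def absolute(a: Tensor) -> Tensor:
    out = np.abs(a.data)
    return Tensor(out, (a,), lambda g: (g * np.sign(a.data),))


def relu(a: Tensor) -> Tensor:
    out = np.maximum(a.data, 0)
    mask = (a.data > 0).astype(_F)
    return Tensor(out, (a,), lambda g: (g * mask,))


def sigmoid(a: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-a.data.astype(np.float64)))
    out = out.astype(_F)
    return Tensor(out, (a,), lambda g: (g * out * (1.0 - out),))


def mean_all(a: Tensor) -> Tensor:
    n = a.data.size
    return Tensor(a.data.mean(), (a,), lambda g: (np.full(a.shape, 1.0 / n, dtype=_F) * g,))


def sum_all(a: Tensor) -> Tensor:
    return Tensor(a.data.sum(), (a,), lambda g: (np.full(a.shape, 1.0, dtype=_F) * g,))


def mean_axes(a: Tensor, axes: tuple[int, ...], keepdims: bool = True) -> Tensor:
    out = a.data.mean(axis=axes, keepdims=keepdims)
    n = int(np.prod([a.shape[ax] for ax in axes]))

    def _bwd(g):
        gg = g if keepdims else np.expand_dims(g, axes)
        return (np.broadcast_to(gg, a.shape) / n,)

    return Tensor(out, (a,), _bwd)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bwd(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(out, tuple(tensors), _bwd)


# ---------------------------------------------------------------------------
# spatial ops (NCHW layout)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    return windows[:, :, ::stride, ::stride], x.shape  # (N, C, Ho, Wo, kh, kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int | None = None) -> Tensor:
    """2-D cross-correlation: x (N,C,H,W), w (O,C,kh,kw), bias (O,).

    Default padding keeps the spatial size at stride 1 ("same" for odd
    kernels); output size is ``(H + 2p - kh)//stride + 1``.  Implemented as
    im2col + GEMM; the column matrix is materialized once and shared by
    the forward and both backward products.
    """
    n, c, h, wid = x.shape
    o, c2, kh, kw = w.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, weight {c2}")
    if pad is None:
        pad = kh // 2
    windows, padded_shape = _im2col(x.data, kh, kw, stride, pad)
    ho, wo = windows.shape[2], windows.shape[3]
    cols = np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n * ho * wo, c * kh * kw
    )
    wmat = w.data.reshape(o, c * kh * kw)
    out = (cols @ wmat.T).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)
    if b is not None:
        out += b.data[None, :, None, None]

    def _bwd(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
        gw = (gmat.T @ cols).reshape(o, c, kh, kw)
        gcols = (gmat @ wmat).reshape(n, ho, wo, c, kh, kw)
        gx_pad = np.zeros(padded_shape, dtype=_F)
        for i in range(kh):
            for j in range(kw):
                gx_pad[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                    gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        gx = gx_pad[:, :, pad : pad + h, pad : pad + wid] if pad else gx_pad
        gb = g.sum(axis=(0, 2, 3)) if b is not None else None
        return (gx, gw.astype(_F), gb)

    parents = (x, w, b) if b is not None else (x, w)
    if b is None:
        return Tensor(out, parents, lambda g: _bwd(g)[:2])
    return Tensor(out, parents, _bwd)


def maxpool2d(x: Tensor, k: int = 2, stride: int | None = None, pad: int = 0) -> Tensor:
    stride = stride or k
    n, c, h, w = x.shape
    cols, padded_shape = _im2col(x.data, k, k, stride, pad)
    n_, c_, ho, wo, _, _ = cols.shape
    flat = cols.reshape(n_, c_, ho, wo, k * k)
    arg = flat.argmax(axis=4)
    out = np.take_along_axis(flat, arg[..., None], axis=4)[..., 0]

    def _bwd(g):
        gx_pad = np.zeros(padded_shape, dtype=_F)
        iy, ix = np.divmod(arg, k)
        oy = np.arange(ho)[None, None, :, None] * stride
        ox = np.arange(wo)[None, None, None, :] * stride
        rows = (oy + iy).ravel()
        colsx = (ox + ix).ravel()
        ni = np.repeat(np.arange(n_), c_ * ho * wo)
        ci = np.tile(np.repeat(np.arange(c_), ho * wo), n_)
        np.add.at(gx_pad, (ni, ci, rows, colsx), g.ravel())
        return (gx_pad[:, :, pad : pad + h, pad : pad + w] if pad else gx_pad,)

    return Tensor(out, (x,), _bwd)


def avgpool2d(x: Tensor, k: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError("avgpool2d requires divisible spatial size")
    out = x.data.reshape(n, c, h // k, k, w // k, k).mean(axis=(3, 5))

    def _bwd(g):
        gx = np.repeat(np.repeat(g, k, axis=2), k, axis=3) / (k * k)
        return (gx,)

    return Tensor(out, (x,), _bwd)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centres)."""
    m = np.zeros((n_out, n_in), dtype=_F)
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = (src - lo).astype(_F)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    return m


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Separable bilinear resize expressed as two small matrix products."""
    n, c, h, w = x.shape
    oh, ow = out_hw
    if (oh, ow) == (h, w):
        return x
    ay = _interp_matrix(oh, h)
    ax = _interp_matrix(ow, w)
    # separable resize as two matmuls: rows then columns
    out = np.matmul(ay[None, None], np.matmul(x.data, ax.T))

    def _bwd(g):
        return (np.matmul(ay.T[None, None], np.matmul(g, ax)),)

    return Tensor(out, (x,), _bwd)


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization; updates running stats in place."""
    if training:
        axes = (0, 2, 3)
        m = x.data.mean(axis=axes)
        v = x.data.var(axis=axes)
        running_mean *= 1.0 - momentum
        running_mean += momentum * m
        running_var *= 1.0 - momentum
        running_var += momentum * v
    else:
        m, v = running_mean, running_var
    inv = 1.0 / np.sqrt(v + eps)
    xhat = (x.data - m[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    n_elem = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def _bwd(g):
        gg = gamma.data[None, :, None, None]
        dxhat = g * gg
        if training:
            s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
            s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
            dx = (inv[None, :, None, None] / n_elem) * (n_elem * dxhat - s1 - xhat * s2)
        else:
            dx = dxhat * inv[None, :, None, None]
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        return (dx.astype(_F), dgamma.astype(_F), dbeta.astype(_F))

    return Tensor(out.astype(_F), (x, gamma, beta), _bwd)


def l1_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean absolute per-pixel difference to a constant target."""
    t = Tensor(target)
    return mean_all(absolute(sub(pred, t)))


def bce_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy on [0,1] activations against [0,1] targets."""
    p = np.clip(pred.data.astype(np.float64), eps, 1.0 - eps)
    t = np.asarray(target, dtype=np.float64)
    val = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()

    def _bwd(g):
        return ((g * (p - t) / (p * (1.0 - p)) / p.size).astype(_F),)

    return Tensor(np.float32(val), (pred,), _bwd)
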