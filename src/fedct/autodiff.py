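"""Minimal reverse-mode automatic differentiation on numpy arrays.

The networks in this package are small (tens of thousands of parameters) and
run on CPU, so a compact tape-based engine is sufficient: a :class:`Tensor`
wraps an ``ndarray`` and records its parents plus a backward closure;
:meth:`Tensor.backward` topologically sorts the tape and accumulates
gradients.  Convolutions are im2col + BLAS matmul; their input gradient is
computed as a convolution of the (dilated, padded) output gradient with the
flipped kernel so that everything stays matmul-bound.

Only the operations the reconstruction networks need are provided; each one
is gradient-checked in the test suite against central finite differences.
"""

from __future__ import annotations

from typing import Callable, Optional, Sequence

import numpy as np

DTYPE = np.float32


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Optional[Callable] = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self._parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    # operator sugar -------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, _as_tensor(-1.0)))

    def __neg__(self):
        return mul(self, _as_tensor(-1.0))

    def backward(self, grad: Optional[np.ndarray] = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = g.astype(DTYPE, copy=False)
    # gradients are never mutated in place, so aliasing a view here is safe
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == tuple(shape):
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def power(a: Tensor, p: float) -> Tensor:
    out = Tensor(a.data ** p, parents=(a,))

    def backward(g):
        _accum(a, g * p * a.data ** (p - 1))

    out._backward = backward
    return out


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out_data = a.data.mean(axis=axis, keepdims=keepdims)
    out = Tensor(out_data, parents=(a,))
    n = a.data.size if axis is None else np.prod(
        [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])

    def backward(g):
        gg = np.asarray(g)
        if not keepdims and axis is not None:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.shape) / n)

    out._backward = backward
    return out


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,))

    def backward(g):
        gg = np.asarray(g)
        if not keepdims and axis is not None:
            gg = np.expand_dims(gg, axis)
        _accum(a, np.broadcast_to(gg, a.shape).astype(DTYPE))

    out._backward = backward
    return out


def leaky_relu(a: Tensor, slope: float = 0.2) -> Tensor:
    neg = a.data * slope
    out_data = np.maximum(a.data, neg)
    out = Tensor(out_data, parents=(a,))

    def backward(g):
        grad = np.where(a.data > 0, g, g * slope)
        _accum(a, grad)

    out._backward = backward
    return out


def group_norm(x: Tensor, gamma: Tensor, beta: Tensor, n_groups: int,
               eps: float = 1e-5) -> Tensor:
    """Fused group normalisation over (N, C, H, W) with per-channel affine."""
    n, c, h, w = x.shape
    g_ = n_groups if c % n_groups == 0 else 1
    xg = x.data.reshape(n, g_, -1)
    mu = xg.mean(axis=2, keepdims=True)
    xc = xg - mu
    var = (xc * xc).mean(axis=2, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    y = (xc * inv).reshape(n, c, h, w)
    out_data = y * gamma.data.reshape(1, c, 1, 1) + beta.data.reshape(1, c, 1, 1)
    out = Tensor(out_data, parents=(x, gamma, beta))

    def backward(g):
        if gamma.requires_grad:
            _accum(gamma, (g * y).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gy = (g * gamma.data.reshape(1, c, 1, 1)).reshape(n, g_, -1)
            yg = y.reshape(n, g_, -1)
            m1 = gy.mean(axis=2, keepdims=True)
            m2 = (gy * yg).mean(axis=2, keepdims=True)
            gx = inv * (gy - m1 - yg * m2)
            _accum(x, gx.reshape(n, c, h, w).astype(DTYPE))

    out._backward = backward
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(s, parents=(a,))

    def backward(g):
        _accum(a, g * s * (1.0 - s))

    out._backward = backward
    return out


def reshape(a: Tensor, shape) -> Tensor:
    out = Tensor(a.data.reshape(shape), parents=(a,))

    def backward(g):
        _accum(a, g.reshape(a.shape))

    out._backward = backward
    return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            _accum(t, piece)

    out._backward = backward
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, parents=(a, b))

    def backward(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

# Tap-loop convolutions beat im2col here: the networks are narrow (few
# channels), so the column gather dominates any BLAS gain.  The threshold is
# kept as a switch for wide-channel configurations.
_TAP_THRESHOLD = 10_000


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """Padded (N, C, H, W) -> columns (N*Ho*Wo, C*kh*kw)."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _conv2d_raw(x: np.ndarray, w: np.ndarray, stride: int,
                pad_h: int, pad_w: int, return_cols: bool = False):
    """Convolution via im2col + BLAS (large kernels) or shift-slice taps."""
    if pad_h or pad_w:
        x = np.pad(x, ((0, 0), (0, 0), (pad_h, pad_h), (pad_w, pad_w)))
    n, c, h, ww = x.shape
    o, _, kh, kw = w.shape
    if kh * kw > _TAP_THRESHOLD or return_cols:
        cols, ho, wo = _im2col(x, kh, kw, stride)
        out = (cols @ w.reshape(o, -1).T).reshape(n, ho, wo, o)
        out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
        return (out, cols) if return_cols else out
    ho = (h - kh) // stride + 1
    wo = (ww - kw) // stride + 1
    out = np.zeros((n, ho, wo, o), dtype=DTYPE)
    for di in range(kh):
        for dj in range(kw):
            xs = x[:, :, di:di + (ho - 1) * stride + 1:stride,
                   dj:dj + (wo - 1) * stride + 1:stride]
            out += np.moveaxis(xs, 1, -1) @ w[:, :, di, dj].T
    out = np.ascontiguousarray(np.moveaxis(out, -1, 1))
    return (out, None) if return_cols else out


def _conv2d_wgrad_taps(x: np.ndarray, g: np.ndarray, kh: int, kw: int,
                       stride: int, pad_h: int, pad_w: int) -> np.ndarray:
    if pad_h or pad_w:
        x = np.pad(x, ((0, 0), (0, 0), (pad_h, pad_h), (pad_w, pad_w)))
    o = g.shape[1]
    c = x.shape[1]
    ho, wo = g.shape[2], g.shape[3]
    gw = np.empty((o, c, kh, kw), dtype=DTYPE)
    gt = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(o, -1)
    for di in range(kh):
        for dj in range(kw):
            xs = x[:, :, di:di + (ho - 1) * stride + 1:stride,
                   dj:dj + (wo - 1) * stride + 1:stride]
            xt = np.ascontiguousarray(xs.transpose(1, 0, 2, 3)).reshape(c, -1)
            gw[:, :, di, dj] = gt @ xt.T
    return gw


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding=None) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    ``padding`` defaults to 'same' for stride 1 (odd kernels); pass an
    ``(ph, pw)`` pair for explicit padding.
    """
    o, c, kh, kw = w.shape
    if x.shape[1] != c:
        raise ValueError(f"conv2d channel mismatch: input {x.shape[1]}, kernel {c}")
    if padding is None:
        pad_h, pad_w = kh // 2, kw // 2
    else:
        pad_h, pad_w = padding
    n = x.shape[0]
    use_cols = kh * kw > _TAP_THRESHOLD
    if use_cols:
        out_data, cols = _conv2d_raw(x.data, w.data, stride, pad_h, pad_w,
                                     return_cols=True)
    else:
        out_data, cols = _conv2d_raw(x.data, w.data, stride, pad_h, pad_w), None
    ho, wo = out_data.shape[2], out_data.shape[3]
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
        parents = (x, w, b)
    else:
        parents = (x, w)
    out = Tensor(out_data, parents=parents)

    def backward(g):
        if w.requires_grad:
            if use_cols and cols is not None:
                g_flat = np.ascontiguousarray(
                    g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, o)
                _accum(w, (g_flat.T @ cols).reshape(w.shape))
            else:
                _accum(w, _conv2d_wgrad_taps(x.data, g, kh, kw, stride,
                                             pad_h, pad_w))
        if b is not None and b.requires_grad:
            _accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if stride > 1:  # dilate the output gradient
                gd = np.zeros(
                    (n, o, (ho - 1) * stride + 1, (wo - 1) * stride + 1),
                    dtype=DTYPE)
                gd[:, :, ::stride, ::stride] = g
            else:
                gd = g
            w_flip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
            gx_full = _conv2d_raw(gd, w_flip, 1, kh - 1, kw - 1)
            h_in, w_in = x.shape[2], x.shape[3]
            gx = gx_full[:, :, pad_h:pad_h + h_in, pad_w:pad_w + w_in]
            if gx.shape[2] < h_in or gx.shape[3] < w_in:  # stride remainder
                gx = np.pad(gx, ((0, 0), (0, 0),
                                 (0, h_in - gx.shape[2]),
                                 (0, w_in - gx.shape[3])))
            _accum(x, gx)

    out._backward = backward
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    out_data = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        n, c, h, w = x.shape
        gg = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        _accum(x, gg)

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# losses and fixed linear physics operators
# ---------------------------------------------------------------------------

def huber(diff: Tensor, delta: float) -> Tensor:
    """Mean Huber penalty of a residual tensor: quadratic core, linear tails."""
    a = diff.data
    absa = np.abs(a)
    quad = absa <= delta
    vals = np.where(quad, 0.5 * a ** 2, delta * (absa - 0.5 * delta))
    out = Tensor(vals.mean(), parents=(diff,))

    def backward(g):
        _accum(diff, g * np.clip(a, -delta, delta) / a.size)

    out._backward = backward
    return out


def tv_aniso(x: Tensor) -> Tensor:
    """Anisotropic total variation: mean |forward difference| on both axes
    of the last two dimensions."""
    d = x.data
    dy = d[..., 1:, :] - d[..., :-1, :]
    dx = d[..., :, 1:] - d[..., :, :-1]
    total = np.abs(dy).sum() + np.abs(dx).sum()
    n = dy.size + dx.size
    out = Tensor(total / max(n, 1), parents=(x,))

    def backward(g):
        gx = np.zeros_like(d)
        sy = np.sign(dy) / max(n, 1)
        sx = np.sign(dx) / max(n, 1)
        gx[..., 1:, :] += sy
        gx[..., :-1, :] -= sy
        gx[..., :, 1:] += sx
        gx[..., :, :-1] -= sx
        _accum(x, g * gx)

    out._backward = backward
    return out


def linear_op(x: Tensor, apply_fn, transpose_fn, batched: bool = True) -> Tensor:
    """Fixed linear operator (e.g. back-projection) with exact adjoint gradient.

    ``apply_fn`` maps a single 2-D array to a 2-D array; ``transpose_fn`` is
    its adjoint.  With ``batched`` the op maps (N, 1, H, W) -> (N, 1, H', W').
    """
    if batched:
        outs = [apply_fn(x.data[i, 0]) for i in range(x.shape[0])]
        out_data = np.stack(outs)[:, None].astype(DTYPE)
    else:
        out_data = apply_fn(x.data).astype(DTYPE)
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        if batched:
            gs = [transpose_fn(g[i, 0]) for i in range(g.shape[0])]
            _accum(x, np.stack(gs)[:, None].astype(DTYPE))
        else:
            _accum(x, transpose_fn(g).astype(DTYPE))

    out._backward = backward
    return out


def mse(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return mean(power(a - b, 2.0))
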