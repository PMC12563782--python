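"""Convolution, pooling and loss primitives with hand-written backward passes.

All kernels use im2col views plus BLAS matmuls; the input gradient of a
strided convolution is computed as a stride-1 convolution of the
zero-dilated output gradient with the flipped kernel, so no scatter-add
appears on the hot path.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d_2x2",
    "max_pool2d",
    "upsample_nearest2d",
    "softmax_cross_entropy",
    "bce_with_logits",
    "softmax",
]


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> contiguous (C*kh*kw, N*Ho*Wo) patch matrix."""
    n, c, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    sn, sc, sh, sw = xp.strides
    view = as_strided(
        xp,
        shape=(c, kh, kw, n, ho, wo),
        strides=(sc, sh, sw, sn, sh * stride, sw * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(c * kh * kw, n * ho * wo), ho, wo


def _conv_raw(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    """Cross-correlation. x (N,C,H,W), w (Co,C,kh,kw) -> (N,Co,Ho,Wo)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    co, ci, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw, stride)
    out = np.matmul(w.reshape(co, ci * kh * kw), cols)  # (Co, N*Ho*Wo)
    out = out.reshape(co, x.shape[0], ho, wo).swapaxes(0, 1)
    return out, cols


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, padding: int = 0) -> Tensor:
    out, cols = _conv_raw(x.data, w.data, stride, padding)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    else:
        out = np.ascontiguousarray(out)
    need = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    co, ci, kh, kw = w.data.shape
    n, _, h, wdt = x.data.shape

    def _bw(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gm = np.ascontiguousarray(g.swapaxes(0, 1)).reshape(co, -1)
            dw = gm @ cols.T
            w._accumulate(dw.reshape(w.data.shape))
        if x.requires_grad:
            ho, wo = g.shape[2], g.shape[3]
            if stride > 1:
                gd = np.zeros(
                    (n, co, (ho - 1) * stride + 1, (wo - 1) * stride + 1), dtype=g.dtype
                )
                gd[:, :, ::stride, ::stride] = g
            else:
                gd = g
            hp, wp = h + 2 * padding, wdt + 2 * padding
            eh = hp - (gd.shape[2] + kh - 1)
            ew = wp - (gd.shape[3] + kw - 1)
            gd = np.pad(
                gd, ((0, 0), (0, 0), (kh - 1, kh - 1 + eh), (kw - 1, kw - 1 + ew))
            )
            wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (Ci,Co,kh,kw)
            dxp, _ = _conv_raw(gd, wf, 1, 0)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    prev = tuple(t for t in (x, w, b) if t is not None)
    return Tensor(out, need, _bw if need else None, prev if need else ())


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2 stride-2 transposed convolution (the U-Net up-sampling step).

    Windows never overlap at kernel=stride=2, so both directions reduce
    to a single einsum.  w has shape (Cin, Cout, 2, 2).
    """
    n, ci, h, wd = x.data.shape
    _, co, _, _ = w.data.shape
    out = np.einsum("nihw,iokl->nohkwl", x.data, w.data, optimize=True)
    out = out.reshape(n, co, 2 * h, 2 * wd)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)
    need = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)

    def _bw(g):
        gw = g.reshape(n, co, h, 2, wd, 2).transpose(0, 1, 2, 4, 3, 5)  # n,o,h,w,k,l
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            w._accumulate(np.einsum("nihw,nohwkl->iokl", x.data, gw, optimize=True))
        if x.requires_grad:
            x._accumulate(np.einsum("nohwkl,iokl->nihw", gw, w.data, optimize=True))

    prev = tuple(t for t in (x, w, b) if t is not None)
    return Tensor(out, need, _bw if need else None, prev if need else ())


def max_pool2d(x: Tensor, kernel: int, stride: int | None = None, padding: int = 0) -> Tensor:
    stride = stride or kernel
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2), constant_values=-np.inf)
    n, c, hp, wp = xp.shape
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    sn, sc, sh, sw = xp.strides
    win = as_strided(
        xp,
        shape=(n, c, ho, wo, kernel, kernel),
        strides=(sn, sc, sh * stride, sw * stride, sh, sw),
        writeable=False,
    ).reshape(n, c, ho, wo, kernel * kernel)
    arg = win.argmax(axis=-1)
    out = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]

    def _bw(g):
        dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
        ii, cc, hh, ww = np.indices((n, c, ho, wo), sparse=False)
        hi = hh * stride + arg // kernel
        wi = ww * stride + arg % kernel
        np.add.at(dxp, (ii, cc, hi, wi), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    need = x.requires_grad
    return Tensor(out, need, _bw if need else None, (x,) if need else ())


def upsample_nearest2d(x: Tensor, factor: int = 2) -> Tensor:
    out = x.data.repeat(factor, axis=2).repeat(factor, axis=3)
    n, c, h, w = x.data.shape

    def _bw(g):
        x._accumulate(
            g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
        )

    need = x.requires_grad
    return Tensor(out, need, _bw if need else None, (x,) if need else ())


def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch norm over (N,H,W) per channel.

    Returns ``(out, batch_mean, batch_var)`` with the standard backward.
    """
    xd = x.data
    axes = (0, 2, 3)
    m = xd.shape[0] * xd.shape[2] * xd.shape[3]
    mu = xd.mean(axis=axes, keepdims=True)
    xc = xd - mu
    var = np.mean(xc * xc, axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xn = xc * inv
    out = xn * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)

    def _bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accumulate((g * xn).sum(axis=axes))
        if x.requires_grad:
            gxn = g * gamma.data.reshape(1, -1, 1, 1)
            t1 = gxn.mean(axis=axes, keepdims=True)
            t2 = (gxn * xn).mean(axis=axes, keepdims=True)
            x._accumulate(inv * (gxn - t1 - xn * t2))

    need = x.requires_grad or gamma.requires_grad or beta.requires_grad
    t = Tensor(out, need, _bw if need else None, (x, gamma, beta) if need else ())
    return t, mu.reshape(-1), var.reshape(-1)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean pixel-wise cross entropy. logits (N,K,...), labels int (N,...)."""
    k = logits.data.shape[1]
    lg = np.moveaxis(logits.data, 1, -1).reshape(-1, k)
    lab = labels.reshape(-1)
    if lab.min() < 0 or lab.max() >= k:
        raise ValueError(f"labels outside [0,{k})")
    z = lg - lg.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = (lse - z[np.arange(lab.size), lab]).mean()

    def _bw(g):
        p = softmax(lg, axis=1)
        p[np.arange(lab.size), lab] -= 1.0
        p *= g / lab.size
        dl = p.reshape(labels.shape + (k,))
        logits._accumulate(np.moveaxis(dl, -1, 1))

    need = logits.requires_grad
    return Tensor(np.asarray(loss), need, _bw if need else None, (logits,) if need else ())


def bce_with_logits(logits: Tensor, targets: np.ndarray, weight: np.ndarray | None = None) -> Tensor:
    x, t = logits.data, targets
    raw = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))
    if weight is not None:
        raw = raw * weight
    loss = raw.mean()

    def _bw(g):
        s = 1.0 / (1.0 + np.exp(-x))
        d = (s - t)
        if weight is not None:
            d = d * weight
        logits._accumulate(g * d / x.size)

    need = logits.requires_grad
    return Tensor(np.asarray(loss), need, _bw if need else None, (logits,) if need else ())
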