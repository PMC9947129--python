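"""Differentiable array operations used by the restoration network.

All spatial operations use the NCHW layout.  ``conv2d`` performs
cross-correlation (the deep-learning convention) with zero padding;
symmetric (edge-mirroring) padding is available separately via
:func:`pad2d_symmetric` for filters that must not see artificial black
borders, e.g. the Sobel operator inside the edge loss.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor

__all__ = [
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "batch_norm2d",
    "pad2d_symmetric",
]


def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,H,W) -> (N*oh*ow, C*kh*kw) patch matrix."""
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    n, c, oh, ow = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw), oh, ow


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution: a pure channel-mixing matmul."""
    xd = x.data
    n, c, h, wd_ = xd.shape
    o = w.data.shape[0]
    wm = w.data.reshape(o, c)
    out = np.matmul(wm, xd.reshape(n, c, h * wd_)).reshape(n, o, h, wd_)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gr = g.reshape(n, o, h * wd_)
        if w.requires_grad:
            dw = np.einsum("nox,ncx->oc", gr, xd.reshape(n, c, h * wd_),
                           optimize=True)
            Tensor._accum(w, dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dx = np.matmul(wm.T, gr).reshape(n, c, h, wd_)
            Tensor._accum(x, dx)

    return Tensor._result(out, parents, bwd)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation. x: (N,C,H,W); w: (O,C,kh,kw); b: (O,)."""
    if w.data.shape[2] == 1 and w.data.shape[3] == 1 and stride == 1 \
            and padding == 0:
        return _conv1x1(x, w, b)
    xd = x.data
    if padding:
        xd = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n = xd.shape[0]
    o, c, kh, kw = w.data.shape
    cols, oh, ow = _im2col(xd, kh, kw, stride)
    out = cols @ w.data.reshape(o, -1).T
    out = out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, o)
        if w.requires_grad:
            Tensor._accum(w, (gm.T @ cols).reshape(w.data.shape))
        if b is not None and b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            if stride == 1:
                # dX = full correlation of the upstream gradient with the
                # spatially flipped, channel-transposed weights
                wf = w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
                gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1),
                                (kw - 1, kw - 1)))
                gcols, gh, gw = _im2col(gp, kh, kw, 1)
                dxp = (gcols @ wf.reshape(c, -1).T).reshape(
                    n, gh, gw, c).transpose(0, 3, 1, 2)
            else:
                dcols = (gm @ w.data.reshape(o, -1)).reshape(n, oh, ow, c, kh, kw)
                dxp = np.zeros_like(xd)
                for i in range(kh):
                    for j in range(kw):
                        dxp[:, :, i:i + oh * stride:stride,
                            j:j + ow * stride:stride] += \
                            dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            Tensor._accum(x, np.ascontiguousarray(dxp))

    return Tensor._result(out, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 2) -> Tensor:
    """Transposed convolution with kernel size == stride (non-overlapping
    up-convolution).  x: (N,C,H,W); w: (C, O, s, s); output (N,O,H*s,W*s)."""
    xd = x.data
    n, c, h, wd_ = xd.shape
    _, o, kh, kw = w.data.shape
    if kh != stride or kw != stride:
        raise ValueError("kernel size must equal stride")
    out = np.zeros((n, o, h * stride, wd_ * stride), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i::stride, j::stride] = np.einsum(
                "nchw,co->nohw", xd, w.data[:, :, i, j], optimize=True)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        if x.requires_grad:
            dx = np.zeros_like(xd)
            for i in range(kh):
                for j in range(kw):
                    dx += np.einsum("nohw,co->nchw", g[:, :, i::stride, j::stride],
                                    w.data[:, :, i, j], optimize=True)
            Tensor._accum(x, dx)
        if w.requires_grad:
            dw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    dw[:, :, i, j] = np.einsum(
                        "nchw,nohw->co", xd, g[:, :, i::stride, j::stride],
                        optimize=True)
            Tensor._accum(w, dw)
        if b is not None and b.requires_grad:
            Tensor._accum(b, g.sum(axis=(0, 2, 3)))

    return Tensor._result(out, parents, bwd)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2. Spatial dims must be even."""
    xd = x.data
    n, c, h, w = xd.shape
    if h % 2 or w % 2:
        raise ValueError("max_pool2d requires even spatial dimensions")
    windows = xd.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = windows.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        if not x.requires_grad:
            return
        dflat = np.zeros_like(flat)
        np.put_along_axis(dflat, idx[..., None], g[..., None], axis=-1)
        dx = dflat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        Tensor._accum(x, dx.reshape(n, c, h, w))

    return Tensor._result(out, (x,), bwd)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalization over (N,H,W).

    In training mode the batch statistics are used and the running buffers
    are updated in place; in eval mode the running buffers are used and
    treated as constants in the backward pass.
    """
    xd = x.data
    shape = (1, -1, 1, 1)
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= (1.0 - momentum)
        running_mean += momentum * mu
        running_var *= (1.0 - momentum)
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(shape)) * inv_std.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def bwd(g):
        if gamma.requires_grad:
            Tensor._accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            Tensor._accum(beta, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data.reshape(shape) * inv_std.reshape(shape)
            if training:
                m = g.mean(axis=(0, 2, 3), keepdims=True)
                mx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                Tensor._accum(x, gs * (g - m - xhat * mx))
            else:
                Tensor._accum(x, gs * g)

    return Tensor._result(out, (x, gamma, beta), bwd)


def _symmetric_index(n: int, pad: int) -> np.ndarray:
    idx = np.arange(-pad, n + pad)
    idx = np.where(idx < 0, -idx - 1, idx)
    idx = np.where(idx >= n, 2 * n - idx - 1, idx)
    return idx


def pad2d_symmetric(x: Tensor, pad: int) -> Tensor:
    """Edge-mirroring padding (numpy 'symmetric' convention) on H and W."""
    xd = x.data
    n, c, h, w = xd.shape
    if pad > h or pad > w:
        raise ValueError("padding exceeds image size")
    iy = _symmetric_index(h, pad)
    ix = _symmetric_index(w, pad)
    out = xd[:, :, iy[:, None], ix[None, :]]

    def bwd(g):
        if not x.requires_grad:
            return
        tmp = np.zeros((n, c, h, w + 2 * pad), dtype=g.dtype)
        for i_out, i_src in enumerate(iy):
            tmp[:, :, i_src, :] += g[:, :, i_out, :]
        dx = np.zeros_like(xd)
        for j_out, j_src in enumerate(ix):
            dx[:, :, :, j_src] += tmp[:, :, :, j_out]
        Tensor._accum(x, dx)

    return Tensor._result(out, (x,), bwd)
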