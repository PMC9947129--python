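"""Differentiable counterparts of the evaluation metrics.

These functions build the training objective inside the autodiff graph on
NCHW tensors.  They follow the same definitions as :mod:`endorestore.metrics`
(SSIM with a Gaussian window over valid positions, PSNR deficit against a
50 dB reference, pixel MSE, Sobel edge-magnitude difference on luminance);
small epsilon guards keep logarithms and square roots finite so gradients
flow even at a perfect reconstruction.
"""

from __future__ import annotations

import numpy as np

from .metrics import (PSNR_LOSS_REF_DB, SSIM_SIGMA, SSIM_WINDOW, LossReport,
                      LossWeights)
from .nn import Tensor
from .nn import functional as F

__all__ = ["mse_t", "psnr_loss_t", "ssim_t", "edge_loss_t", "composite_loss"]

_SOBEL_BANK = np.stack([
    np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]),
    np.array([[-1.0, -2.0, -1.0], [0.0, 0.0, 0.0], [1.0, 2.0, 1.0]]),
])[:, None, :, :]  # (2, 1, 3, 3)

_LOG10 = float(np.log(10.0))


def mse_t(pred: Tensor, target: Tensor) -> Tensor:
    return ((pred - target) ** 2).mean()


def psnr_loss_t(pred: Tensor, target: Tensor,
                ref_db: float = PSNR_LOSS_REF_DB) -> Tensor:
    """Normalized PSNR deficit max(0, (ref - PSNR)/ref) for unit-range data."""
    err = mse_t(pred, target) + 1e-12
    psnr_db = (-10.0 / _LOG10) * err.log()
    return ((ref_db - psnr_db) * (1.0 / ref_db)).relu()


def _window_mean(x: Tensor, win_row: Tensor, win_col: Tensor) -> Tensor:
    """Depthwise 'valid' correlation with the separable Gaussian window."""
    n, c, h, w = x.shape
    flat = x.reshape(n * c, 1, h, w)
    out = F.conv2d(F.conv2d(flat, win_row, padding=0), win_col, padding=0)
    oh, ow = out.shape[2], out.shape[3]
    return out.reshape(n, c, oh, ow)


def ssim_t(pred: Tensor, target: Tensor, window: int = SSIM_WINDOW,
           sigma: float = SSIM_SIGMA) -> Tensor:
    """Mean SSIM over channels and valid window positions (differentiable)."""
    half = (window - 1) // 2
    xs = np.arange(-half, half + 1, dtype=np.float64)
    g1 = np.exp(-0.5 * (xs / sigma) ** 2)
    g1 /= g1.sum()
    g1 = g1.astype(pred.data.dtype)
    win_row = Tensor(g1.reshape(1, 1, 1, window))
    win_col = Tensor(g1.reshape(1, 1, window, 1))
    mu_a = _window_mean(pred, win_row, win_col)
    mu_b = _window_mean(target, win_row, win_col)
    s_aa = _window_mean(pred * pred, win_row, win_col)
    s_bb = _window_mean(target * target, win_row, win_col)
    s_ab = _window_mean(pred * target, win_row, win_col)
    var_a = s_aa - mu_a * mu_a
    var_b = s_bb - mu_b * mu_b
    cov = s_ab - mu_a * mu_b
    c1, c2 = 0.01 ** 2, 0.03 ** 2
    s = ((mu_a * mu_b * 2.0 + c1) * (cov * 2.0 + c2)) / \
        ((mu_a * mu_a + mu_b * mu_b + c1) * (var_a + var_b + c2))
    return s.mean()


def _sobel_mag_t(img: Tensor) -> Tensor:
    lum = img.mean(axis=1, keepdims=True)
    padded = F.pad2d_symmetric(lum, 1)
    bank = Tensor(_SOBEL_BANK.astype(img.data.dtype))
    g = F.conv2d(padded, bank, padding=0)          # (N, 2, H, W)
    return (g * g).sum(axis=1, keepdims=True).sqrt()


def edge_loss_t(pred: Tensor, target: Tensor) -> Tensor:
    return (_sobel_mag_t(pred) - _sobel_mag_t(target)).abs().mean()


def composite_loss(pred: Tensor, target: Tensor,
                   weights: LossWeights = LossWeights(),
                   ssim_window: int = SSIM_WINDOW
                   ) -> tuple[Tensor, LossReport]:
    """Weighted training loss plus a float report of the individual terms.

    Terms with zero weight are skipped entirely, so the coarse stage never
    pays for the Sobel filtering it does not use.
    """
    terms: dict[str, float] = {"l_ssim": 0.0, "l_psnr": 0.0,
                               "l_2": 0.0, "l_edge": 0.0}
    total: Tensor | None = None

    def add(term: Tensor, weight: float, name: str):
        nonlocal total
        terms[name] = term.item()
        if weight > 0:
            contrib = term * weight
            total = contrib if total is None else total + contrib

    if weights.w_ssim > 0:
        add(1.0 - ssim_t(pred, target, window=ssim_window), weights.w_ssim, "l_ssim")
    if weights.w_psnr > 0:
        add(psnr_loss_t(pred, target), weights.w_psnr, "l_psnr")
    if weights.w_l2 > 0:
        add(mse_t(pred, target), weights.w_l2, "l_2")
    if weights.w_edge > 0:
        add(edge_loss_t(pred, target), weights.w_edge, "l_edge")
    if total is None:
        total = Tensor(np.zeros((), dtype=pred.data.dtype))
    report = LossReport(l_ssim=terms["l_ssim"], l_psnr=terms["l_psnr"],
                        l_2=terms["l_2"], l_edge=terms["l_edge"],
                        total=total.item())
    return total, report
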