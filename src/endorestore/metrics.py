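"""Image-quality metrics and the composite restoration loss report.

All metrics operate on float images in ``[0, 1]``, shaped ``(H, W)`` or
``(H, W, C)``.  SSIM follows the Wang et al. formulation: an 11x11 Gaussian
window (sigma 1.5), K1 = 0.01, K2 = 0.03, population (weighted-moment)
covariances, dynamic range 1; color images are scored per channel and
averaged.  PSNR is capped at 100 dB when the MSE underflows so that
identical images produce a finite score.

The composite loss mirrors the training objective: a structural term
``1 - SSIM``, a normalized PSNR deficit ``max(0, (50 - PSNR)/50)``, the
plain mean squared error, and a Sobel edge-difference term used during
fine-tuning to sharpen motion-blurred frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import DimensionError, ParameterError

__all__ = [
    "PSNR_CAP_DB",
    "PSNR_LOSS_REF_DB",
    "SSIM_WINDOW",
    "SSIM_SIGMA",
    "mse",
    "psnr",
    "ssim",
    "edge_loss",
    "LossWeights",
    "LossReport",
    "total_loss",
]

PSNR_CAP_DB = 100.0      # reported PSNR for (near-)identical images
PSNR_LOSS_REF_DB = 50.0  # reference level for the PSNR-deficit loss term
SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03

_SOBEL_X = np.array([[-1.0, 0.0, 1.0],
                     [-2.0, 0.0, 2.0],
                     [-1.0, 0.0, 1.0]])
_SOBEL_Y = _SOBEL_X.T


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def mse(a: np.ndarray, b: np.ndarray) -> float:
    """Mean squared error over every value of the pair."""
    a, b = _check_pair(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(max^2 / MSE), in dB."""
    if max_val <= 0:
        raise ParameterError("max_val must be positive")
    err = mse(a, b)
    if err < 1e-12:
        return PSNR_CAP_DB
    return float(10.0 * np.log10(max_val * max_val / err))


def gaussian_window(size: int = SSIM_WINDOW, sigma: float = SSIM_SIGMA) -> np.ndarray:
    """Normalized 2-D Gaussian weighting window."""
    half = (size - 1) // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    return np.outer(g, g)


def _ssim_single(a: np.ndarray, b: np.ndarray, win: np.ndarray) -> float:
    """SSIM of one 2-D channel, averaged over fully valid windows."""
    size = win.shape[0]
    wa = sliding_window_view(a, (size, size))
    wb = sliding_window_view(b, (size, size))
    mu_a = np.einsum("hwij,ij->hw", wa, win, optimize=True)
    mu_b = np.einsum("hwij,ij->hw", wb, win, optimize=True)
    s_aa = np.einsum("hwij,ij->hw", wa * wa, win, optimize=True)
    s_bb = np.einsum("hwij,ij->hw", wb * wb, win, optimize=True)
    s_ab = np.einsum("hwij,ij->hw", wa * wb, win, optimize=True)
    var_a = s_aa - mu_a ** 2
    var_b = s_bb - mu_b ** 2
    cov = s_ab - mu_a * mu_b
    c1 = _SSIM_K1 ** 2
    c2 = _SSIM_K2 ** 2
    s = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / \
        ((mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2))
    return float(s.mean())


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity; 1.0 for identical images."""
    a, b = _check_pair(a, b)
    if min(a.shape[0], a.shape[1]) < SSIM_WINDOW:
        raise DimensionError(
            f"image sides must be >= the {SSIM_WINDOW}-pixel SSIM window")
    win = gaussian_window()
    if a.ndim == 2:
        return _ssim_single(a, b, win)
    vals = [_ssim_single(a[..., c], b[..., c], win) for c in range(a.shape[-1])]
    return float(np.mean(vals))


def _luminance(img: np.ndarray) -> np.ndarray:
    return img if img.ndim == 2 else img.mean(axis=-1)


def sobel_magnitude(img: np.ndarray) -> np.ndarray:
    """Sobel gradient magnitude of the channel-averaged luminance,
    with edge-mirroring boundary handling."""
    lum = _luminance(np.asarray(img, dtype=np.float64))
    gx = ndimage.correlate(lum, _SOBEL_X, mode="reflect")
    gy = ndimage.correlate(lum, _SOBEL_Y, mode="reflect")
    return np.hypot(gx, gy)


def edge_loss(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference of Sobel gradient magnitudes."""
    a, b = _check_pair(a, b)
    return float(np.mean(np.abs(sobel_magnitude(a) - sobel_magnitude(b))))


@dataclass(frozen=True)
class LossWeights:
    """Multipliers of the four loss terms."""

    w_ssim: float = 1.0
    w_psnr: float = 1.0
    w_l2: float = 1.0
    w_edge: float = 0.0

    def __post_init__(self):
        for name in ("w_ssim", "w_psnr", "w_l2", "w_edge"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @classmethod
    def coarse(cls) -> "LossWeights":
        return cls(1.0, 1.0, 1.0, 0.0)

    @classmethod
    def fine(cls) -> "LossWeights":
        return cls(1.0, 1.0, 1.0, 1.0)


@dataclass(frozen=True)
class LossReport:
    l_ssim: float
    l_psnr: float
    l_2: float
    l_edge: float
    total: float


def total_loss(pred: np.ndarray, target: np.ndarray,
               weights: LossWeights = LossWeights()) -> LossReport:
    """Composite restoration loss; exactly zero when pred equals target."""
    l_ssim = 1.0 - ssim(pred, target)
    l_psnr = max(0.0, (PSNR_LOSS_REF_DB - psnr(pred, target)) / PSNR_LOSS_REF_DB)
    l_2 = mse(pred, target)
    l_edge = edge_loss(pred, target)
    total = (weights.w_ssim * l_ssim + weights.w_psnr * l_psnr
             + weights.w_l2 * l_2 + weights.w_edge * l_edge)
    return LossReport(l_ssim=l_ssim, l_psnr=l_psnr, l_2=l_2,
                      l_edge=l_edge, total=total)
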