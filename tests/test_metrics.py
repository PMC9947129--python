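"""Metric definitions against analytic cases, reference implementations,
and their differentiable counterparts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endorestore import (DimensionError, LossWeights, edge_loss, mse, psnr,
                         ssim, total_loss)
from endorestore.losses import composite_loss, edge_loss_t, mse_t, ssim_t
from endorestore.metrics import PSNR_CAP_DB, sobel_magnitude
from endorestore.nn import Tensor

SOBEL_X = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]])


def _to_nchw(img):
    return Tensor(np.asarray(img).transpose(2, 0, 1)[None])


# -- analytic cases ---------------------------------------------------------

def test_mse_analytic_cases():
    a = np.zeros((4, 4, 3))
    assert mse(a, a) == 0.0
    assert mse(a, np.ones_like(a)) == 1.0
    assert mse(np.array([0.0, 0.5]), np.array([0.5, 1.0])) == 0.25


def test_psnr_analytic_cases():
    a = np.zeros((8, 8, 3))
    b = np.full_like(a, 0.5)
    assert psnr(a, a) == PSNR_CAP_DB
    # MSE equal to max^2 gives exactly 0 dB
    assert abs(psnr(np.zeros((4, 4)), np.ones((4, 4)), max_val=1.0)) < 1e-12
    assert abs(psnr(a, b) - 10 * np.log10(4.0)) < 1e-12   # ~6.0206 dB


def test_ssim_identical_and_constant_pairs():
    a = np.full((16, 16, 3), 0.5)
    assert ssim(a, a) == pytest.approx(1.0)
    rnd = np.random.default_rng(0).random((32, 32, 3))
    assert ssim(rnd, rnd) == pytest.approx(1.0)


def test_edge_loss_flat_images_and_identity(rng):
    a = rng.random((16, 16, 3))
    assert edge_loss(a, a) == 0.0
    assert edge_loss(np.full((16, 16, 3), 0.2),
                     np.full((16, 16, 3), 0.9)) < 1e-15


def test_shape_mismatch_raises():
    with pytest.raises(DimensionError):
        mse(np.zeros((4, 4)), np.zeros((4, 5)))
    with pytest.raises(DimensionError):
        ssim(np.zeros((8, 8, 3)), np.zeros((8, 8, 3)))  # below window size


# -- reference oracles ------------------------------------------------------

def test_ssim_matches_reference_implementation(rng):
    from skimage.metrics import structural_similarity

    for _ in range(10):
        a = rng.random((32, 32, 3))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        ref = np.mean([structural_similarity(
            a[..., c], b[..., c], gaussian_weights=True, sigma=1.5,
            use_sample_covariance=False, data_range=1.0) for c in range(3)])
        assert ssim(a, b) == pytest.approx(ref, abs=1e-6)


def test_psnr_matches_reference_implementation(rng):
    from skimage.metrics import peak_signal_noise_ratio

    for _ in range(10):
        a = rng.random((32, 32, 3))
        b = rng.random((32, 32, 3))
        assert psnr(a, b) == pytest.approx(
            peak_signal_noise_ratio(a, b, data_range=1.0), abs=1e-6)


def _brute_sobel_magnitude(img):
    lum = img.mean(axis=-1)
    padded = np.pad(lum, 1, mode="symmetric")
    h, w = lum.shape
    gx = np.zeros_like(lum)
    gy = np.zeros_like(lum)
    for y in range(h):
        for x in range(w):
            win = padded[y:y + 3, x:x + 3]
            gx[y, x] = np.sum(win * SOBEL_X)
            gy[y, x] = np.sum(win * SOBEL_X.T)
    return np.sqrt(gx ** 2 + gy ** 2)


def test_edge_loss_matches_nested_loop_sobel(rng):
    step = np.zeros((16, 16, 3))
    step[:, 8:, :] = 0.8
    from scipy.ndimage import gaussian_filter
    blurred = gaussian_filter(step, sigma=(1.5, 1.5, 0))
    want = np.mean(np.abs(_brute_sobel_magnitude(step)
                          - _brute_sobel_magnitude(blurred)))
    assert edge_loss(step, blurred) == pytest.approx(want, abs=1e-10)
    # and the exported magnitude itself
    np.testing.assert_allclose(sobel_magnitude(step),
                               _brute_sobel_magnitude(step), atol=1e-10)


# -- symmetry / bounds properties ------------------------------------------

@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_metric_symmetry_and_bounds(seed):
    r = np.random.default_rng(seed)
    a = r.random((16, 16, 3))
    b = r.random((16, 16, 3))
    assert mse(a, b) == mse(b, a)
    assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)
    assert edge_loss(a, b) == pytest.approx(edge_loss(b, a), abs=1e-12)
    assert -1.0 <= ssim(a, b) <= 1.0
    rep = total_loss(a, b, LossWeights.fine())
    assert min(rep.l_ssim, rep.l_psnr, rep.l_2, rep.l_edge) >= 0
    assert rep.total >= 0


def test_total_loss_zero_on_identical_inputs(rng):
    x = rng.random((16, 16, 3))
    for w in (LossWeights.coarse(), LossWeights.fine(), LossWeights(0, 0, 0, 0)):
        assert total_loss(x, x, w).total == 0.0


def test_total_loss_recombines_terms(image_pair):
    a, b = image_pair
    w = LossWeights(0.7, 1.3, 2.0, 0.5)
    rep = total_loss(a, b, w)
    assert rep.l_ssim == pytest.approx(1.0 - ssim(a, b), abs=1e-12)
    assert rep.l_2 == pytest.approx(mse(a, b), abs=1e-12)
    assert rep.l_edge == pytest.approx(edge_loss(a, b), abs=1e-12)
    assert rep.l_psnr == pytest.approx(max(0.0, (50 - psnr(a, b)) / 50), abs=1e-12)
    hand = (0.7 * rep.l_ssim + 1.3 * rep.l_psnr + 2.0 * rep.l_2
            + 0.5 * rep.l_edge)
    assert rep.total == pytest.approx(hand, abs=1e-9)


def test_negative_weight_rejected():
    from endorestore import ParameterError
    with pytest.raises(ParameterError):
        LossWeights(w_ssim=-0.1)


# -- differentiable counterparts -------------------------------------------

def test_graph_losses_agree_with_numpy_metrics(image_pair):
    a, b = image_pair
    at, bt = _to_nchw(a), _to_nchw(b)
    assert ssim_t(at, bt).item() == pytest.approx(ssim(a, b), abs=1e-9)
    assert mse_t(at, bt).item() == pytest.approx(mse(a, b), abs=1e-12)
    assert edge_loss_t(at, bt).item() == pytest.approx(edge_loss(a, b),
                                                       abs=1e-9)
    _, rep = composite_loss(at, bt, LossWeights.fine())
    want = total_loss(a, b, LossWeights.fine())
    assert rep.total == pytest.approx(want.total, abs=1e-6)


@pytest.mark.parametrize("size,window", [(8, 7), (16, 11)])
def test_composite_loss_gradient_flow(size, window, rng):
    """Finite-difference check that every loss term passes gradients to the
    prediction."""
    x = rng.random((1, 3, size, size))
    y = rng.random((1, 3, size, size))
    xt = Tensor(x.copy(), requires_grad=True)
    loss, _ = composite_loss(xt, Tensor(y), LossWeights.fine(),
                             ssim_window=window)
    loss.backward()
    assert np.any(xt.grad != 0)
    eps = 1e-6
    for idx in [(0, 0, 0, 0), (0, 1, size // 2, size // 2),
                (0, 2, size - 1, size - 1)]:
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        lp, _ = composite_loss(Tensor(xp), Tensor(y), LossWeights.fine(),
                               ssim_window=window)
        lm, _ = composite_loss(Tensor(xm), Tensor(y), LossWeights.fine(),
                               ssim_window=window)
        num = (lp.item() - lm.item()) / (2 * eps)
        assert xt.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


def test_psnr_of_degraded_phantom_nonincreasing_in_sigma():
    """Averaged over seeds, heavier Gaussian noise never raises PSNR."""
    from endorestore import NoiseSpec, add_noise
    from endorestore.phantom import PhantomConfig, generate_phantom

    sigmas = [10, 20, 30, 40, 50, 60]
    means = []
    for sigma in sigmas:
        vals = []
        for seed in range(20):
            clean = generate_phantom(PhantomConfig(seed=seed, height=32,
                                                   width=32))
            noisy = add_noise(clean, NoiseSpec(family="gaussian",
                                               sigma=float(sigma), seed=seed))
            vals.append(psnr(noisy, clean))
        means.append(np.mean(vals))
    assert all(means[i] >= means[i + 1] for i in range(len(means) - 1))
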