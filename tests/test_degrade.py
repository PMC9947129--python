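"""Forward degradation model: kernels, blur, noise statistics, color cast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endorestore import (ColorCast, DegradationSpec, NoiseSpec, ParameterError,
                         add_noise, apply_blur, apply_color_cast, degrade,
                         invert_color_cast, make_motion_kernel)
from endorestore.phantom import PhantomConfig, generate_phantom


# -- motion kernels ---------------------------------------------------------

def test_length_one_is_identity_kernel():
    for angle in (0.0, 30.0, 90.0, 179.0):
        k = make_motion_kernel(1, angle)
        np.testing.assert_array_equal(k.grid, [[1.0]])


def test_horizontal_kernel_is_uniform_line():
    k = make_motion_kernel(5, 0.0)
    assert k.grid.shape == (1, 5)
    np.testing.assert_allclose(k.grid, np.full((1, 5), 0.2), atol=1e-12)


def test_vertical_kernel_is_transpose_of_horizontal():
    h = make_motion_kernel(7, 0.0)
    v = make_motion_kernel(7, 90.0)
    np.testing.assert_allclose(v.grid, h.grid.T, atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(length=st.integers(1, 15), angle=st.floats(0.0, 179.99))
def test_kernels_normalized_and_nonnegative(length, angle):
    k = make_motion_kernel(length, angle)
    assert abs(k.grid.sum() - 1.0) < 1e-9
    assert (k.grid >= 0).all()


def test_kernel_rejects_bad_parameters():
    with pytest.raises(ParameterError):
        make_motion_kernel(0, 0.0)
    with pytest.raises(ParameterError):
        make_motion_kernel(5, 180.0)


# -- blur -------------------------------------------------------------------

def _brute_force_convolve(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """True convolution with symmetric (edge-mirroring) padding, by loops."""
    kh, kw = kernel.shape
    ph, pw = kh // 2, kw // 2
    flipped = kernel[::-1, ::-1]
    out = np.zeros_like(img)
    for c in range(img.shape[-1]):
        padded = np.pad(img[..., c], ((ph, ph), (pw, pw)), mode="symmetric")
        for y in range(img.shape[0]):
            for x in range(img.shape[1]):
                out[y, x, c] = np.sum(padded[y:y + kh, x:x + kw] * flipped)
    return out


def test_blur_matches_nested_loop_convolution(rng):
    img = rng.random((16, 16, 3))
    for length, angle in [(5, 0.0), (5, 45.0), (7, 120.0)]:
        k = make_motion_kernel(length, angle)
        got = apply_blur(img, k)
        want = _brute_force_convolve(img, k.grid)
        np.testing.assert_allclose(got, want, atol=1e-10)


def test_blur_identity_kernel_and_constant_image(rng):
    img = rng.random((16, 16, 3))
    np.testing.assert_allclose(apply_blur(img, make_motion_kernel(1, 0.0)),
                               img, atol=1e-12)
    const = np.full((16, 16, 3), 0.37)
    np.testing.assert_allclose(apply_blur(const, make_motion_kernel(7, 30.0)),
                               const, atol=1e-12)


def test_blur_preserves_mean_intensity(rng):
    img = rng.random((64, 64, 3))
    out = apply_blur(img, make_motion_kernel(9, 60.0))
    assert abs(out.mean() - img.mean()) < 1e-3


def test_blur_rejects_oversized_kernel():
    with pytest.raises(ParameterError):
        apply_blur(np.zeros((4, 4, 3)), make_motion_kernel(9, 0.0))


# -- noise ------------------------------------------------------------------

def test_gaussian_noise_std_matches_sigma():
    img = np.full((256, 256, 3), 0.5)
    out = add_noise(img, NoiseSpec(family="gaussian", sigma=25.5, seed=0))
    measured = (out - img).std()
    assert abs(measured - 0.1) < 0.003  # sigma/255 = 0.1, within 3%


def test_salt_pepper_corruption_fraction_within_binomial_interval():
    img = np.full((100, 100, 3), 0.5)
    out = add_noise(img, NoiseSpec(family="salt_pepper", amount=0.1,
                                   salt_fraction=0.5, seed=1))
    corrupted = np.sum((out[..., 0] == 0.0) | (out[..., 0] == 1.0))
    # central 95% binomial interval for n=10000, p=0.1
    n, p = 10000, 0.1
    half = 1.96 * np.sqrt(n * p * (1 - p))
    assert n * p - half < corrupted < n * p + half


@pytest.mark.parametrize("family,param,rel_tol", [
    ("gaussian", {"sigma": 20.0}, None),
    ("speckle", {"variance": 0.04}, None),
    ("poisson", {"peak": 200.0}, None),
])
def test_noise_moments_over_seeds(family, param, rel_tol):
    """Empirical moments on large constant images match nominal parameters
    within 3-sigma sampling bounds, aggregated over seeds."""
    img = np.full((128, 128, 3), 0.4)
    n_vals = img.size
    devs = []
    for seed in range(20):
        out = add_noise(img, NoiseSpec(family=family, seed=seed, **param))
        devs.append(out - img)
    dev = np.stack(devs)
    if family == "gaussian":
        nominal = 20.0 / 255.0
        assert abs(dev.std() - nominal) < 3 * nominal / np.sqrt(2 * n_vals)
    elif family == "speckle":
        nominal = np.sqrt(0.04) * 0.4       # std of img * N(0, var)
        assert abs(dev.std() - nominal) < 3 * nominal / np.sqrt(2 * n_vals)
    else:  # poisson: mean ~ input, var ~ input/peak
        assert abs(dev.mean()) < 3 * np.sqrt(0.4 / 200.0 / (20 * n_vals))
        nominal_var = 0.4 / 200.0
        assert abs(dev.var() - nominal_var) < 0.05 * nominal_var


def test_noise_none_and_determinism(rng):
    img = rng.random((32, 32, 3))
    np.testing.assert_array_equal(add_noise(img, NoiseSpec(family="none")), img)
    spec = NoiseSpec(family="gaussian", sigma=30.0, seed=42)
    np.testing.assert_array_equal(add_noise(img, spec), add_noise(img, spec))


def test_unknown_noise_family_rejected():
    with pytest.raises(ParameterError):
        NoiseSpec(family="perlin")


# -- color cast -------------------------------------------------------------

def test_color_cast_identity_and_arithmetic():
    img = np.full((4, 4, 3), 0.25)
    ident = ColorCast()
    np.testing.assert_array_equal(apply_color_cast(img, ident), img)
    out = apply_color_cast(img, ColorCast(gains=(2.0, 1.0, 1.0), gamma=1.0))
    np.testing.assert_allclose(out[..., 0], 0.5)
    np.testing.assert_allclose(out[..., 1:], 0.25)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(gr=st.floats(0.6, 1.4), gb=st.floats(0.6, 1.4),
       gamma=st.floats(0.7, 1.4))
def test_color_cast_roundtrip_exact_without_clipping(gr, gb, gamma):
    rng = np.random.default_rng(5)
    img = 0.2 + 0.4 * rng.random((8, 8, 3))   # stays clear of clipping
    cast = ColorCast(gains=(gr, 1.0, gb), gamma=gamma)
    back = invert_color_cast(apply_color_cast(img, cast), cast)
    np.testing.assert_allclose(back, img, atol=1e-12)


def test_color_cast_rejects_nonpositive_parameters():
    with pytest.raises(ParameterError):
        ColorCast(gains=(0.0, 1.0, 1.0))
    with pytest.raises(ParameterError):
        ColorCast(gamma=-1.0)


# -- composition ------------------------------------------------------------

def test_empty_spec_is_identity(rng):
    img = rng.random((24, 24, 3))
    spec = DegradationSpec()
    assert spec.is_identity
    np.testing.assert_array_equal(degrade(img, spec), img)


def test_cast_only_spec_equals_direct_cast(rng):
    img = rng.random((24, 24, 3))
    cast = ColorCast(gains=(1.2, 1.0, 0.8), gamma=1.1)
    np.testing.assert_array_equal(
        degrade(img, DegradationSpec(cast=cast)),
        apply_color_cast(img, cast))


def test_full_spec_deterministic_on_phantom():
    img = generate_phantom(PhantomConfig(seed=11, height=32, width=32))
    spec = DegradationSpec(
        cast=ColorCast(gains=(1.15, 1.0, 0.9), gamma=1.05),
        kernel=make_motion_kernel(5, 30.0),
        noise=NoiseSpec(family="gaussian", sigma=20.0, seed=7))
    np.testing.assert_array_equal(degrade(img, spec), degrade(img, spec))
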