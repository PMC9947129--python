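"""Forward degradation model: color cast, motion blur, sensor noise.

Clean frames are corrupted the way an arthroscope corrupts them: the raw
sensor's per-channel response (a gain/gamma color cast, the inverse of the
white-balance correction the restoration must learn), optical/motion blur
(convolution with a normalized line point-spread function), and finally
additive sensor noise — Gaussian, speckle, salt-and-pepper, or Poisson.
The fixed composition order cast -> blur -> noise mirrors that physical
chain: color response is scene-side, blur is optical, noise is added at
the sensor.  All stages clip to [0, 1]; clipping is part of the model,
since real frames show both saturated and underexposed regions.

Gaussian sigma values are quoted on the conventional 0-255 intensity scale
and divided by 255 internally for unit-range images.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError

__all__ = [
    "MotionKernel",
    "NoiseSpec",
    "ColorCast",
    "DegradationSpec",
    "make_motion_kernel",
    "apply_blur",
    "add_noise",
    "apply_color_cast",
    "invert_color_cast",
    "degrade",
    "describe_spec",
]

NOISE_FAMILIES = ("gaussian", "speckle", "salt_pepper", "poisson", "none")


@dataclass(frozen=True)
class MotionKernel:
    """Normalized line point-spread function (houses the blur operator)."""

    grid: np.ndarray
    length: int
    angle: float

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=np.float64)
        if (g < 0).any():
            raise ParameterError("kernel entries must be non-negative")
        if abs(g.sum() - 1.0) > 1e-9:
            raise ParameterError("kernel must sum to 1")
        object.__setattr__(self, "grid", g)


def make_motion_kernel(length: int, angle: float) -> MotionKernel:
    """Rasterize an anti-aliased line of `length` pixels at `angle` degrees.

    The line passes through the kernel center; cells get a weight that
    falls off linearly with perpendicular distance and tapers at the line
    ends, then the grid is cropped to its non-zero bounding box and
    normalized to unit sum.  ``length=1`` is the identity kernel.
    """
    if int(length) != length or length < 1:
        raise ParameterError("length must be an integer >= 1")
    if not (0.0 <= angle < 180.0):
        raise ParameterError("angle must lie in [0, 180)")
    length = int(length)
    if length == 1:
        return MotionKernel(grid=np.array([[1.0]]), length=1, angle=float(angle))

    side = length if length % 2 == 1 else length + 1
    half = side // 2
    offsets = np.arange(side) - half
    yy, xx = np.meshgrid(offsets, offsets, indexing="ij")
    theta = np.deg2rad(angle)
    ux, uy = np.cos(theta), np.sin(theta)
    proj = xx * ux + yy * uy
    perp = np.abs(-xx * uy + yy * ux)
    across = np.clip(1.0 - perp, 0.0, 1.0)
    along = np.clip((length + 1) / 2.0 - np.abs(proj), 0.0, 1.0)
    grid = across * along
    grid[grid < 1e-12] = 0.0   # drop float crumbs from near-axis angles
    rows = np.flatnonzero(grid.sum(axis=1) > 0)
    cols = np.flatnonzero(grid.sum(axis=0) > 0)
    grid = grid[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    grid = grid / grid.sum()
    return MotionKernel(grid=grid, length=length, angle=float(angle))


def apply_blur(img: np.ndarray, kernel: MotionKernel) -> np.ndarray:
    """Per-channel 2-D convolution with edge-mirroring boundary handling."""
    img = np.asarray(img, dtype=np.float64)
    kh, kw = kernel.grid.shape
    if kh > img.shape[0] or kw > img.shape[1]:
        raise ParameterError("kernel larger than image")
    if img.ndim == 2:
        out = ndimage.convolve(img, kernel.grid, mode="reflect")
    else:
        out = np.stack([ndimage.convolve(img[..., c], kernel.grid, mode="reflect")
                        for c in range(img.shape[-1])], axis=-1)
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class NoiseSpec:
    """One noise draw: family, level parameters, and the RNG seed.

    ``sigma`` is the Gaussian standard deviation on the 0-255 scale;
    ``variance`` the unit-scale speckle variance; ``amount`` the fraction of
    corrupted pixel positions (of which ``salt_fraction`` become white);
    ``peak`` the expected photon count of a unit-intensity pixel for
    Poisson noise.
    """

    family: str = "none"
    sigma: float = 25.0
    variance: float = 0.05
    amount: float = 0.05
    salt_fraction: float = 0.5
    peak: float = 255.0
    seed: int = 0

    def __post_init__(self):
        if self.family not in NOISE_FAMILIES:
            raise ParameterError(
                f"unknown noise family {self.family!r}; expected one of "
                f"{NOISE_FAMILIES}")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")
        if not (0.0 <= self.amount <= 1.0):
            raise ParameterError("amount must lie in [0, 1]")
        if not (0.0 <= self.salt_fraction <= 1.0):
            raise ParameterError("salt_fraction must lie in [0, 1]")
        if self.variance < 0:
            raise ParameterError("variance must be >= 0")
        if self.peak <= 0:
            raise ParameterError("peak must be positive")


def add_noise(img: np.ndarray, spec: NoiseSpec) -> np.ndarray:
    """Apply one seeded noise draw; output clipped to [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if spec.family == "none":
        return img.copy()
    rng = np.random.default_rng(spec.seed)
    if spec.family == "gaussian":
        out = img + rng.normal(0.0, spec.sigma / 255.0, size=img.shape)
    elif spec.family == "speckle":
        out = img * (1.0 + rng.normal(0.0, np.sqrt(spec.variance), size=img.shape))
    elif spec.family == "salt_pepper":
        out = img.copy()
        hw = img.shape[:2]
        hit = rng.random(hw) < spec.amount
        salt = rng.random(hw) < spec.salt_fraction
        out[hit & salt] = 1.0
        out[hit & ~salt] = 0.0
        return out
    elif spec.family == "poisson":
        counts = rng.poisson(np.clip(img, 0.0, 1.0) * spec.peak)
        out = counts / spec.peak
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class ColorCast:
    """Per-channel gain and gamma emulating a raw, unbalanced sensor."""

    gains: tuple[float, float, float] = (1.0, 1.0, 1.0)
    gamma: float = 1.0

    def __post_init__(self):
        if any(g <= 0 for g in self.gains):
            raise ParameterError("gains must be positive")
        if self.gamma <= 0:
            raise ParameterError("gamma must be positive")


def apply_color_cast(img: np.ndarray, cast: ColorCast) -> np.ndarray:
    """out_c = clip((img_c * gain_c) ** gamma)."""
    img = np.asarray(img, dtype=np.float64)
    out = (img * np.asarray(cast.gains)) ** cast.gamma
    return np.clip(out, 0.0, 1.0)


def invert_color_cast(img: np.ndarray, cast: ColorCast) -> np.ndarray:
    """Analytic inverse (gamma first, then gains); exact where the forward
    transform did not clip."""
    img = np.asarray(img, dtype=np.float64)
    return (img ** (1.0 / cast.gamma)) / np.asarray(cast.gains)


@dataclass(frozen=True)
class DegradationSpec:
    """Full parameterization of one corruption draw.

    Composition order is fixed: color cast, then blur, then noise.  A spec
    with no cast, no kernel and noise family 'none' is the identity map.
    """

    cast: ColorCast | None = None
    kernel: MotionKernel | None = None
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def with_seed(self, seed: int) -> "DegradationSpec":
        return dataclasses.replace(
            self, noise=dataclasses.replace(self.noise, seed=int(seed)))

    @property
    def is_identity(self) -> bool:
        return self.cast is None and self.kernel is None \
            and self.noise.family == "none"


def degrade(img: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Apply a full degradation draw; deterministic in ``spec.noise.seed``."""
    out = np.asarray(img, dtype=np.float64)
    if spec.cast is not None:
        out = apply_color_cast(out, spec.cast)
    if spec.kernel is not None:
        out = apply_blur(out, spec.kernel)
    out = add_noise(out, spec.noise)
    return out


def describe_spec(spec: DegradationSpec) -> tuple[str, float]:
    """(family label, level) used to group evaluation cells.

    The label concatenates 'blur' and/or the noise family; the level is
    the blur length when blur is present, otherwise the dominant noise
    level parameter.
    """
    parts = []
    if spec.cast is not None:
        parts.append("cast")
    if spec.kernel is not None:
        parts.append("blur")
    if spec.noise.family != "none":
        parts.append(spec.noise.family)
    label = "+".join(parts) if parts else "identity"
    if spec.kernel is not None:
        level = float(spec.kernel.length)
    elif spec.noise.family == "gaussian":
        level = float(spec.noise.sigma)
    elif spec.noise.family == "speckle":
        level = float(spec.noise.variance)
    elif spec.noise.family == "salt_pepper":
        level = float(spec.noise.amount)
    elif spec.noise.family == "poisson":
        level = float(spec.noise.peak)
    else:
        level = 0.0
    return label, level
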