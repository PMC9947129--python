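"""Procedural tissue-phantom frames for training and testing.

Real arthroscopic footage shows smooth, low-texture tissue surfaces under
strongly non-uniform illumination: a bright center falling off toward the
frame border (vignetting from the scope's co-axial light source), a few
sharp anatomical boundaries (meniscus and ligament edges), occasional
saturated specular highlights from wet tissue, and an overall color bias
that depends on the illuminant (halogen vs. white micro-LED).  Those
footage statistics — not anatomy — are what the generator emulates, so the
training pipeline needs no external data.

A frame is assembled as: smooth per-channel Gaussian random fields on a
reddish tissue tint, plus a few soft blobs, one to three sharp shading
boundaries, a multiplicative polynomial vignette, per-channel illuminant
gains, clipping to [0, 1], and finally a Poisson-distributed number of
small specular disks set to exactly 1.0.  Every frame is a pure function
of its config (counter-based Philox streams), so datasets of any size are
bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import DimensionError, ParameterError

__all__ = ["PhantomConfig", "generate_phantom", "generate_dataset",
           "Manifest", "ManifestRecord", "load_image", "save_image"]

ILLUMINANT_GAINS = {
    "warm": (1.12, 1.00, 0.82),   # halogen-like, red-heavy
    "cool": (0.86, 1.00, 1.12),   # white-LED-like, blue-heavy
}


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic frame.

    ``texture_scale`` is the correlation length (pixels) of the smooth
    intensity fields; ``specular_density`` is the expected number of
    saturated highlight disks per frame; ``vignette_strength`` in [0, 1]
    scales the center-to-corner illumination falloff.
    """

    seed: int = 0
    height: int = 64
    width: int = 64
    n_blobs: int = 6
    vignette_strength: float = 0.5
    specular_density: float = 1.5
    texture_scale: float = 8.0
    illuminant: str = "warm"

    def __post_init__(self):
        if self.height < 16 or self.width < 16:
            raise DimensionError("phantom frames must be at least 16x16")
        if self.illuminant not in ILLUMINANT_GAINS:
            raise ParameterError(
                f"illuminant must be one of {sorted(ILLUMINANT_GAINS)}")
        if not (0.0 <= self.vignette_strength <= 1.0):
            raise ParameterError("vignette_strength must lie in [0, 1]")
        if self.specular_density < 0 or self.n_blobs < 0:
            raise ParameterError("counts must be non-negative")
        if self.texture_scale <= 0:
            raise ParameterError("texture_scale must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        return cls(**d)


def _smooth_field(rng: np.random.Generator, h: int, w: int,
                  scale: float) -> np.ndarray:
    """Unit-variance Gaussian-filtered noise; zero for infinite scale."""
    if np.isinf(scale):
        return np.zeros((h, w))
    field = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma=scale,
                                    mode="wrap")
    std = field.std()
    if std < 1e-12:
        return np.zeros((h, w))
    return field / std


def generate_phantom(config: PhantomConfig) -> np.ndarray:
    """Render one clean frame; deterministic in ``config`` alone.

    Returns an (H, W, 3) float64 RGB image in [0, 1] whose saturated
    specular pixels are exactly 1.0.
    """
    h, w = config.height, config.width
    rng = np.random.Generator(
        np.random.Philox(np.random.SeedSequence(config.seed)))

    # base tissue color: pinkish tint around a per-frame brightness
    brightness = rng.uniform(0.48, 0.85)
    tint = np.array([1.0, 0.62, 0.55]) * rng.uniform(0.85, 1.15, size=3)
    img = np.broadcast_to(brightness * tint, (h, w, 3)).copy()

    # smooth low-frequency texture per channel
    for c in range(3):
        img[..., c] += 0.06 * _smooth_field(rng, h, w, config.texture_scale)

    # soft tissue blobs
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    for _ in range(config.n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        radius = rng.uniform(0.08, 0.30) * min(h, w)
        amp = rng.uniform(-0.16, 0.16)
        color = rng.uniform(0.6, 1.0, size=3)
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * radius ** 2))
        img += amp * bump[..., None] * color

    # sharp shading boundaries (meniscus/ligament-like edges)
    if config.n_blobs > 0:
        for _ in range(int(rng.integers(1, 3))):
            theta = rng.uniform(0, np.pi)
            py, px = rng.uniform(0.25 * h, 0.75 * h), rng.uniform(0.25 * w, 0.75 * w)
            side = (yy - py) * np.sin(theta) + (xx - px) * np.cos(theta) > 0
            shade = 1.0 - rng.uniform(0.05, 0.20)
            img[side] *= shade

    # multiplicative vignette around a jittered optical center
    cy = 0.5 * h * (1 + rng.uniform(-0.1, 0.1))
    cx = 0.5 * w * (1 + rng.uniform(-0.1, 0.1))
    r2 = ((yy - cy) / (0.5 * h)) ** 2 + ((xx - cx) / (0.5 * w)) ** 2
    vignette = 1.0 - config.vignette_strength * np.clip(r2 / 2.0, 0.0, 1.0)
    img *= vignette[..., None]

    img *= np.asarray(ILLUMINANT_GAINS[config.illuminant])
    img = np.clip(img, 0.0, 1.0)

    # saturated specular highlights, set after clipping so they are exactly 1
    n_spec = int(rng.poisson(config.specular_density))
    for _ in range(n_spec):
        sy, sx = rng.uniform(0, h), rng.uniform(0, w)
        radius = rng.uniform(1.0, 3.0)
        mask = (yy - sy) ** 2 + (xx - sx) ** 2 <= radius ** 2
        img[mask] = 1.0

    return img


# ---------------------------------------------------------------------------
# dataset emission

@dataclass(frozen=True)
class ManifestRecord:
    file: str
    seed: int
    config: dict


@dataclass
class Manifest:
    """JSON-lines index of an emitted frame set."""

    root: Path
    records: list[ManifestRecord]

    MANIFEST_NAME = "manifest.jsonl"

    def save(self) -> Path:
        path = Path(self.root) / self.MANIFEST_NAME
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(dataclasses.asdict(rec)) + "\n")
        return path

    @classmethod
    def load(cls, root: str | Path) -> "Manifest":
        root = Path(root)
        records = []
        with open(root / cls.MANIFEST_NAME) as fh:
            for line in fh:
                d = json.loads(line)
                records.append(ManifestRecord(**d))
        return cls(root=root, records=records)

    def __len__(self) -> int:
        return len(self.records)

    def load_images(self) -> list[np.ndarray]:
        return [load_image(Path(self.root) / rec.file) for rec in self.records]


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write a [0,1] float image as 8-bit RGB PNG."""
    arr = np.clip(np.asarray(img), 0.0, 1.0)
    iio.imwrite(Path(path), (np.round(arr * 255.0)).astype(np.uint8))


def load_image(path: str | Path) -> np.ndarray:
    """Read an 8- or 16-bit image as float64 RGB in [0,1]."""
    arr = iio.imread(Path(path))
    if arr.dtype == np.uint8:
        out = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        out = arr.astype(np.float64) / 65535.0
    else:
        out = arr.astype(np.float64)
    if out.ndim == 2:
        out = np.repeat(out[..., None], 3, axis=-1)
    return out[..., :3]


def frame_seeds(base_seed: int, n: int) -> np.ndarray:
    """Per-frame sub-stream seeds derived from one base seed (stable)."""
    ss = np.random.SeedSequence(base_seed)
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def generate_dataset(n: int, base_config: PhantomConfig,
                     out_dir: str | Path) -> Manifest:
    """Write ``n`` PNG frames plus a JSON-lines manifest.

    Frame ``i`` uses a seed derived from ``base_config.seed`` and ``i``;
    re-running with the same arguments reproduces byte-identical files.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = frame_seeds(base_config.seed, n)
    records = []
    for i in range(n):
        cfg = dataclasses.replace(base_config, seed=int(seeds[i]))
        img = generate_phantom(cfg)
        name = f"phantom_{i:05d}.png"
        save_image(out_dir / name, img)
        records.append(ManifestRecord(file=name, seed=int(seeds[i]),
                                      config=cfg.to_dict()))
    manifest = Manifest(root=out_dir, records=records)
    manifest.save()
    return manifest
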