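"""Residual U-Net for one-step frame restoration.

The network learns the mapping from a raw, noisy, blurred observation to
its clean, sharp, white-balanced counterpart as a direct image-to-image
regression.  It is a classic U-Net (encoder halves the spatial dims and
doubles the channels at each level, a bottleneck, and a mirrored decoder
with skip concatenation) whose conv pairs are residual blocks: two 3x3
convolution + batch-norm + ReLU stages summed with an identity shortcut
(1x1-projected when the channel count changes).  Default depth is 4 with
base width 32 (32/64/128/256 and a 512-channel bottleneck); a sigmoid
head guarantees outputs in [0, 1].

Inference accepts frames of any size: inputs are mirror-padded up to the
next multiple of 2**depth and the output is cropped back.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import DimensionError, ParameterError
from .nn import Tensor
from .nn import functional as F

__all__ = ["ModelConfig", "ResidualBlock", "ResUNet", "build_model",
           "restore", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture description.

    ``global_residual`` adds an input -> output skip so the network
    regresses the residual correction rather than the full image (the
    identity map is then free at initialization, which is what makes a
    restoration net trainable quickly); it pairs with the ``clip`` output
    activation.  ``sigmoid`` squashes the raw head output instead and is
    meant for the non-residual variant.
    """

    depth: int = 4
    base_channels: int = 32
    in_channels: int = 3
    out_channels: int = 3
    use_batchnorm: bool = True
    global_residual: bool = True
    final_activation: str = "clip"

    def __post_init__(self):
        if self.depth < 1 or self.base_channels < 1:
            raise ParameterError("depth and base_channels must be >= 1")
        if self.final_activation not in ("sigmoid", "clip"):
            raise ParameterError("final_activation must be 'sigmoid' or 'clip'")
        if self.global_residual and self.in_channels != self.out_channels:
            raise ParameterError(
                "global_residual requires in_channels == out_channels")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


class ResidualBlock(nn.Module):
    """conv-norm-ReLU x2 with an identity (or 1x1-projected) shortcut."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 use_batchnorm: bool = True):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, rng)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, rng)
        self.use_bn = use_batchnorm
        if use_batchnorm:
            self.bn1 = nn.BatchNorm2d(out_ch)
            self.bn2 = nn.BatchNorm2d(out_ch)
        self.proj = None if in_ch == out_ch else nn.Conv2d(in_ch, out_ch, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv1(x)
        if self.use_bn:
            h = self.bn1(h)
        h = h.relu()
        h = self.conv2(h)
        if self.use_bn:
            h = self.bn2(h)
        shortcut = x if self.proj is None else self.proj(x)
        return (h + shortcut).relu()


class ResUNet(nn.Module):
    """Depth-``d`` residual U-Net realizing the restoration mapping."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        self.seed = int(seed)
        self.stage = "init"   # updated by the training pipeline
        rng = np.random.default_rng(seed)
        ch = [config.base_channels * (2 ** i) for i in range(config.depth + 1)]
        self.encoders = []
        in_ch = config.in_channels
        for i in range(config.depth):
            self.encoders.append(
                ResidualBlock(in_ch, ch[i], rng, config.use_batchnorm))
            in_ch = ch[i]
        self.bottleneck = ResidualBlock(ch[config.depth - 1], ch[config.depth],
                                        rng, config.use_batchnorm)
        self.ups = []
        self.decoders = []
        for i in reversed(range(config.depth)):
            self.ups.append(nn.ConvTranspose2d(ch[i + 1], ch[i], rng))
            self.decoders.append(
                ResidualBlock(2 * ch[i], ch[i], rng, config.use_batchnorm))
        self.head = nn.Conv2d(ch[0], config.out_channels, 1, rng)
        if config.global_residual:
            # start exactly at the identity map: the network learns a
            # correction on top of its input
            self.head.weight.data[...] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        m = 2 ** self.config.depth
        if h % m or w % m:
            raise DimensionError(
                f"spatial dims must be divisible by {m}; got {h}x{w} "
                "(use restore() for automatic padding)")
        skips = []
        out = x
        for enc in self.encoders:
            out = enc(out)
            skips.append(out)
            out = F.max_pool2d(out)
        out = self.bottleneck(out)
        for up, dec, skip in zip(self.ups, self.decoders, reversed(skips)):
            out = up(out)
            out = dec(nn.concat([skip, out], axis=1))
        out = self.head(out)
        if self.config.global_residual:
            out = out + x
        if self.config.final_activation == "sigmoid":
            return out.sigmoid()
        return out.clip01()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- checkpointing ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        arrays = {f"a{i}": a for i, a in enumerate(self.state_arrays())}
        meta = json.dumps({"config": asdict(self.config), "seed": self.seed,
                           "stage": self.stage})
        np.savez(Path(path), meta=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "ResUNet":
        path = Path(path)
        if not path.exists():
            raise IOError(f"checkpoint not found: {path}")
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            model = cls(ModelConfig(**meta["config"]), seed=meta["seed"])
            model.stage = meta["stage"]
            for i, arr in enumerate(model.state_arrays()):
                arr[...] = data[f"a{i}"]
        return model


def build_model(config: ModelConfig, seed: int = 0) -> ResUNet:
    """Construct a seeded, He-initialized restoration network."""
    return ResUNet(config, seed=seed)


def load_checkpoint(path: str | Path) -> ResUNet:
    return ResUNet.load(path)


def restore(model: ResUNet, img: np.ndarray) -> np.ndarray:
    """One forward pass on an (H, W, 3) image of arbitrary size.

    The input is mirror-padded to the next multiple of 2**depth, run
    through the network in eval mode, and cropped back; output values lie
    in [0, 1].
    """
    img = np.asarray(img, dtype=np.float32)
    if img.ndim != 3 or img.shape[-1] != model.config.in_channels:
        raise DimensionError(
            f"expected (H, W, {model.config.in_channels}) image, got {img.shape}")
    h, w = img.shape[:2]
    m = 2 ** model.config.depth
    ph = (-h) % m
    pw = (-w) % m
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="symmetric")
    x = Tensor(img.transpose(2, 0, 1)[None])
    was_training = model.training
    model.eval()
    out = model(x).data[0].transpose(1, 2, 0)
    model.train(was_training)
    out = out[:h, :w]
    return np.clip(out.astype(np.float64), 0.0, 1.0)
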