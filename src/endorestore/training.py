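"""Two-stage training pipeline for the restoration network.

Stage one ("coarse") optimizes the composite SSIM + PSNR + L2 loss on
pairs drawn from every degradation family; stage two ("fine") continues
from the coarse weights on the blur-containing subset only, with the Sobel
edge-difference term switched on, so the network learns to recover sharp
edges from their blurred representations.  Both stages use Adam at
learning rate 1e-4 on random patches, and are seeded end to end (split
assignment, data order, patch positions, initialization), so a fixed seed
reproduces the final parameters exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .degrade import DegradationSpec, degrade, describe_spec
from .errors import ConfigurationError, ParameterError
from .losses import composite_loss
from .metrics import LossWeights, ssim
from .model import ResUNet, restore
from .nn import Adam, Tensor
from .phantom import Manifest, load_image, save_image

__all__ = ["TrainConfig", "TrainLog", "PairedDataset", "make_pairs",
           "train_stage", "restore_batch", "derive_pair_seed"]

SPLIT_FRACTIONS = (0.70, 0.15, 0.15)


@dataclass(frozen=True)
class TrainConfig:
    """One training stage.

    ``augment`` enables the four orientation-preserving dihedral
    transforms (identity, horizontal flip, vertical flip, 180-degree
    rotation) on every patch, the standard augmentation for patch-based
    restoration training; each epoch then passes over every
    (pair, transform) combination once.
    """

    stage: str = "coarse"
    epochs: int = 10
    batch_size: int = 8
    patch_size: int = 64
    learning_rate: float = 1e-4
    loss_weights: LossWeights | None = None
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.stage not in ("coarse", "fine"):
            raise ConfigurationError("stage must be 'coarse' or 'fine'")
        if self.epochs < 0 or self.batch_size < 1 or self.patch_size < 1:
            raise ParameterError("epochs/batch_size/patch_size out of range")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.loss_weights is None:
            w = LossWeights.fine() if self.stage == "fine" else LossWeights.coarse()
            object.__setattr__(self, "loss_weights", w)
        if self.stage == "fine" and self.loss_weights.w_edge <= 0:
            raise ConfigurationError(
                "fine stage requires a positive edge-loss weight")


@dataclass
class TrainLog:
    stage: str
    records: list[dict] = field(default_factory=list)

    def append(self, rec: dict) -> None:
        self.records.append(rec)

    def save_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


@dataclass
class Pair:
    clean: np.ndarray       # (H, W, 3) float32
    degraded: np.ndarray    # (H, W, 3) float32
    spec: DegradationSpec
    family: str
    frame_index: int
    split: str

    @property
    def has_blur(self) -> bool:
        return self.spec.kernel is not None


@dataclass
class PairedDataset:
    pairs: list[Pair]

    def subset(self, split: str, blur_only: bool = False) -> list[Pair]:
        return [p for p in self.pairs
                if p.split == split and (p.has_blur or not blur_only)]

    def __len__(self) -> int:
        return len(self.pairs)


def derive_pair_seed(base_seed: int, frame_index: int, spec_index: int) -> int:
    """Stable per-pair noise seed below 2**31."""
    return (base_seed * 1_000_003 + frame_index * 9_973
            + spec_index * 7_919 + 1) % (2 ** 31)


def _assign_splits(n_frames: int, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_frames)
    n_train = int(round(SPLIT_FRACTIONS[0] * n_frames))
    n_val = int(round(SPLIT_FRACTIONS[1] * n_frames))
    labels = [""] * n_frames
    for rank, idx in enumerate(order):
        if rank < n_train:
            labels[idx] = "train"
        elif rank < n_train + n_val:
            labels[idx] = "val"
        else:
            labels[idx] = "test"
    return labels


def make_pairs(clean_manifest: Manifest, degradation_grid: list[DegradationSpec],
               seed: int = 0) -> PairedDataset:
    """Pair every clean frame with every degradation in the grid.

    Frames are split 70/15/15 into train/val/test at the clean-frame
    level, so all degraded versions of one frame share its split and the
    held-out sets never leak training content.
    """
    if len(clean_manifest) == 0:
        raise ParameterError("clean manifest is empty")
    if not degradation_grid:
        raise ParameterError("degradation grid is empty")
    frames = clean_manifest.load_images()
    splits = _assign_splits(len(frames), seed)
    pairs: list[Pair] = []
    for i, frame in enumerate(frames):
        clean32 = frame.astype(np.float32)
        for j, spec in enumerate(degradation_grid):
            seeded = spec.with_seed(derive_pair_seed(seed, i, j))
            deg = degrade(frame, seeded).astype(np.float32)
            family, _ = describe_spec(seeded)
            pairs.append(Pair(clean=clean32, degraded=deg, spec=seeded,
                              family=family, frame_index=i, split=splits[i]))
    return PairedDataset(pairs=pairs)


_DIHEDRAL = (
    lambda a: a,
    lambda a: a[:, ::-1],
    lambda a: a[::-1, :],
    lambda a: a[::-1, ::-1],
)


def _random_patch(pair: Pair, patch: int, rng: np.random.Generator,
                  transform: int = 0):
    h, w = pair.clean.shape[:2]
    if h < patch or w < patch:
        raise ParameterError(
            f"patch_size {patch} exceeds frame size {h}x{w}")
    y = int(rng.integers(0, h - patch + 1))
    x = int(rng.integers(0, w - patch + 1))
    t = _DIHEDRAL[transform]
    return (np.ascontiguousarray(t(pair.degraded[y:y + patch, x:x + patch])),
            np.ascontiguousarray(t(pair.clean[y:y + patch, x:x + patch])))


def _to_nchw(imgs: list[np.ndarray]) -> Tensor:
    arr = np.stack(imgs).transpose(0, 3, 1, 2).astype(np.float32)
    return Tensor(arr)


def train_stage(model: ResUNet, data: PairedDataset,
                config: TrainConfig) -> tuple[ResUNet, TrainLog]:
    """Optimize the composite loss over random patches of the train split.

    Returns the updated model (stage tag advanced) and a per-epoch log of
    the training loss terms plus the validation SSIM.  ``epochs=0``
    validates the configuration and returns the model unchanged.
    """
    if config.stage == "fine" and model.stage == "init":
        raise ConfigurationError(
            "fine-tuning requires a coarse-trained model; run the coarse "
            "stage first")
    blur_only = config.stage == "fine"
    train_pairs = data.subset("train", blur_only=blur_only)
    if not train_pairs:
        raise ConfigurationError(
            f"no training pairs available for stage {config.stage!r}")
    val_pairs = data.subset("val", blur_only=blur_only)

    log = TrainLog(stage=config.stage)
    if config.epochs == 0:
        return model, log

    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    best_val = -np.inf
    best_state: list[np.ndarray] | None = None
    n_aug = len(_DIHEDRAL) if config.augment else 1
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(train_pairs) * n_aug)
        sums = {"l_ssim": 0.0, "l_psnr": 0.0, "l_2": 0.0, "l_edge": 0.0,
                "total": 0.0}
        n_batches = 0
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            xs, ys = zip(*(_random_patch(train_pairs[k % len(train_pairs)],
                                         config.patch_size, rng,
                                         k // len(train_pairs))
                           for k in sel))
            x = _to_nchw(list(xs))
            y = _to_nchw(list(ys))
            pred = model(x)
            loss, report = composite_loss(pred, y, config.loss_weights)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            for k in sums:
                sums[k] += getattr(report, k if k != "total" else "total")
            n_batches += 1
        rec = {"epoch": epoch, "stage": config.stage}
        rec.update({k: v / n_batches for k, v in sums.items()})
        if val_pairs:
            model.eval()
            rec["val_ssim"] = float(np.mean(
                [ssim(restore(model, p.degraded), p.clean) for p in val_pairs]))
            if rec["val_ssim"] > best_val:
                best_val = rec["val_ssim"]
                best_state = [a.copy() for a in model.state_arrays()]
        log.append(rec)
    if best_state is not None:
        # checkpoint selection: keep the epoch with the best validation SSIM
        for dst, src in zip(model.state_arrays(), best_state):
            dst[...] = src
    model.stage = config.stage
    return model, log


def restore_batch(checkpoint: str | Path, in_dir: str | Path,
                  out_dir: str | Path) -> Manifest:
    """Restore every PNG in ``in_dir`` with one forward pass each."""
    from .phantom import ManifestRecord  # local import to avoid cycle noise

    model = ResUNet.load(checkpoint)
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    files = sorted(p.name for p in in_dir.glob("*.png"))
    if not files:
        raise IOError(f"no PNG inputs found in {in_dir}")
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for name in files:
        img = load_image(in_dir / name)
        save_image(out_dir / name, restore(model, img))
        records.append(ManifestRecord(file=name, seed=-1,
                                      config={"checkpoint": str(checkpoint)}))
    manifest = Manifest(root=out_dir, records=records)
    manifest.save()
    return manifest
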