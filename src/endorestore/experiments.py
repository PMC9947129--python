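"""Desk-scale experiment presets.

The full training recipe (thousands of frames, depth-4/base-32 network,
tens of epochs) is far beyond a single CPU, so the package ships one fixed
"tiny profile" that preserves the structure of the method at a size a
laptop can run: ~200 synthetic 64x64 pairs covering every degradation
family (Gaussian sigma 25, speckle, salt-and-pepper, Poisson, three motion
blurs, one blur+noise combination), a depth-2/base-8 network, coarse
training for 10 epochs followed by 5 epochs of blur-only fine-tuning with
the edge term, Adam at 1e-4 throughout.  These sizes are the package's
fixed study conditions — tests and the acceptance script all run this
profile rather than inventing their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .degrade import DegradationSpec, NoiseSpec, make_motion_kernel
from .evaluation import EvalReport, evaluate
from .metrics import ssim
from .model import ModelConfig, ResUNet, build_model, restore
from .phantom import Manifest, PhantomConfig, generate_dataset
from .training import (PairedDataset, TrainConfig, TrainLog, make_pairs,
                       train_stage)

__all__ = ["TINY_FRAME_SIZE", "TINY_N_FRAMES", "tiny_grid",
            "tiny_model_config", "tiny_dataset", "train_tiny",
            "gaussian_sweep_grid", "TinyRunResult", "run_tiny_experiment"]

TINY_FRAME_SIZE = 64
TINY_N_FRAMES = 29          # x 7 grid specs ~= 200 pairs
TINY_COARSE_EPOCHS = 10
TINY_FINE_EPOCHS = 5
TINY_BATCH = 1   # single-sample batches maximize optimizer steps per epoch
                 # at the method's fixed 1e-4 learning rate

EVAL_SIGMA = 25.0           # held-out improvement is measured at this level


def tiny_grid() -> list[DegradationSpec]:
    """All degradation families at one moderate level each."""
    return [
        DegradationSpec(noise=NoiseSpec(family="gaussian", sigma=EVAL_SIGMA)),
        DegradationSpec(noise=NoiseSpec(family="speckle", variance=0.04)),
        DegradationSpec(noise=NoiseSpec(family="salt_pepper", amount=0.05)),
        DegradationSpec(noise=NoiseSpec(family="poisson", peak=100.0)),
        DegradationSpec(kernel=make_motion_kernel(5, 45.0)),
        DegradationSpec(kernel=make_motion_kernel(9, 90.0)),
        DegradationSpec(kernel=make_motion_kernel(7, 0.0),
                        noise=NoiseSpec(family="gaussian", sigma=EVAL_SIGMA)),
    ]


def gaussian_sweep_grid() -> list[DegradationSpec]:
    """Gaussian noise at sigma 10..60 (the benchmark's noise columns)."""
    return [DegradationSpec(noise=NoiseSpec(family="gaussian", sigma=float(s)))
            for s in (10, 20, 30, 40, 50, 60)]


def tiny_model_config() -> ModelConfig:
    return ModelConfig(depth=2, base_channels=8)


def tiny_dataset(seed: int, out_dir: str | Path,
                 n_frames: int = TINY_N_FRAMES
                 ) -> tuple[PairedDataset, Manifest]:
    """Generate phantom frames on disk and pair them with the tiny grid."""
    cfg = PhantomConfig(seed=seed, height=TINY_FRAME_SIZE,
                        width=TINY_FRAME_SIZE)
    manifest = generate_dataset(n_frames, cfg, out_dir)
    return make_pairs(manifest, tiny_grid(), seed=seed), manifest


def train_tiny(data: PairedDataset, seed: int,
               coarse_epochs: int = TINY_COARSE_EPOCHS,
               fine_epochs: int = TINY_FINE_EPOCHS
               ) -> tuple[ResUNet, ResUNet, TrainLog, TrainLog]:
    """Coarse then fine training of the tiny network.

    Returns (coarse model snapshot, fine model, coarse log, fine log).
    The coarse snapshot is a deep copy taken before fine-tuning so the two
    stages can be compared on held-out data.
    """
    model = build_model(tiny_model_config(), seed=seed)
    model, coarse_log = train_stage(model, data, TrainConfig(
        stage="coarse", epochs=coarse_epochs, batch_size=TINY_BATCH,
        patch_size=TINY_FRAME_SIZE, seed=seed))
    coarse_snapshot = _clone(model)
    model, fine_log = train_stage(model, data, TrainConfig(
        stage="fine", epochs=fine_epochs, batch_size=TINY_BATCH,
        patch_size=TINY_FRAME_SIZE, seed=seed + 1))
    return coarse_snapshot, model, coarse_log, fine_log


def _clone(model: ResUNet) -> ResUNet:
    out = build_model(model.config, seed=model.seed)
    out.stage = model.stage
    for dst, src in zip(out.state_arrays(), model.state_arrays()):
        dst[...] = src
    return out


@dataclass
class TinyRunResult:
    """Held-out measurements of one seeded tiny-profile run."""

    seed: int
    ssim_degraded: float        # mean SSIM(degraded, clean) at sigma 25
    ssim_restored: float        # mean SSIM(coarse-restored, clean) at sigma 25
    psnr_degraded: float
    psnr_restored: float
    edge_loss_coarse_blur: float   # mean edge loss on blur-only test pairs
    edge_loss_fine_blur: float
    sweep: EvalReport              # restored SSIM/PSNR across sigma 10..60

    @property
    def ssim_gain(self) -> float:
        return self.ssim_restored - self.ssim_degraded


def run_tiny_experiment(seed: int, workdir: str | Path,
                        sweep: bool = True) -> TinyRunResult:
    """One end-to-end tiny-profile run: data, two-stage training, held-out
    scoring at sigma 25, blur-only edge-loss comparison of the two stages,
    and (optionally) the Gaussian sigma sweep."""
    from .metrics import edge_loss, psnr

    workdir = Path(workdir)
    data, manifest = tiny_dataset(seed, workdir / "frames")
    coarse, fine, _, _ = train_tiny(data, seed)

    test_pairs = data.subset("test")
    sigma_pairs = [p for p in test_pairs
                   if p.family == "gaussian" and p.spec.noise.sigma == EVAL_SIGMA]
    s_deg, s_res, p_deg, p_res = [], [], [], []
    for pair in sigma_pairs:
        rest = restore(coarse, pair.degraded)
        s_deg.append(ssim(pair.degraded, pair.clean))
        s_res.append(ssim(rest, pair.clean))
        p_deg.append(psnr(pair.degraded, pair.clean))
        p_res.append(psnr(rest, pair.clean))

    blur_pairs = data.subset("test", blur_only=True)
    e_coarse = [edge_loss(restore(coarse, p.degraded), p.clean)
                for p in blur_pairs]
    e_fine = [edge_loss(restore(fine, p.degraded), p.clean)
              for p in blur_pairs]

    sweep_report = None
    if sweep:
        test_frames = sorted({p.frame_index for p in test_pairs})
        test_manifest = Manifest(
            root=manifest.root,
            records=[manifest.records[i] for i in test_frames])
        sweep_report = evaluate(fine, test_manifest, gaussian_sweep_grid(),
                                seed=seed)
    return TinyRunResult(
        seed=seed,
        ssim_degraded=float(np.mean(s_deg)),
        ssim_restored=float(np.mean(s_res)),
        psnr_degraded=float(np.mean(p_deg)),
        psnr_restored=float(np.mean(p_res)),
        edge_loss_coarse_blur=float(np.mean(e_coarse)),
        edge_loss_fine_blur=float(np.mean(e_fine)),
        sweep=sweep_report,
    )
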