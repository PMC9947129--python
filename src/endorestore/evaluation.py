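"""SSIM/PSNR evaluation sweeps over degradation families and levels.

For each cell of a degradation grid the harness corrupts every clean
frame, restores it with a trained checkpoint, scores SSIM and PSNR of the
restoration against the clean frame (and of the degraded input, as the
no-restoration baseline), and aggregates mean and standard deviation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .degrade import (ColorCast, DegradationSpec, NoiseSpec, degrade,
                      describe_spec, make_motion_kernel)
from .errors import ParameterError
from .metrics import psnr, ssim
from .model import ResUNet, restore
from .phantom import Manifest
from .training import derive_pair_seed

__all__ = ["EvalReport", "evaluate", "report_to_table", "default_grid"]

_COLUMNS = ["degradation_family", "level", "n_images", "mean_ssim", "std_ssim",
            "mean_psnr", "std_psnr", "mean_ssim_degraded", "mean_psnr_degraded"]


@dataclass
class EvalReport:
    rows: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=_COLUMNS)
        return df.sort_values(["degradation_family", "level"],
                              kind="stable").reset_index(drop=True)

    def cell(self, family: str, level: float) -> dict:
        for row in self.rows:
            if row["degradation_family"] == family and row["level"] == level:
                return row
        raise KeyError((family, level))


def evaluate(model: ResUNet | str | Path, clean_manifest: Manifest,
             grid: list[DegradationSpec], seed: int = 0) -> EvalReport:
    """Score a checkpoint over a degradation grid; deterministic in seed."""
    if isinstance(model, (str, Path)):
        model = ResUNet.load(model)
    if len(clean_manifest) == 0:
        raise ParameterError("clean manifest is empty")
    if not grid:
        raise ParameterError("degradation grid is empty")
    frames = clean_manifest.load_images()
    report = EvalReport(metadata={
        "dataset_seed": seed,
        "n_frames": len(frames),
        "checkpoint_stage": model.stage,
        "grid_size": len(grid),
    })
    for j, spec in enumerate(grid):
        ssim_r, psnr_r, ssim_d, psnr_d = [], [], [], []
        for i, clean in enumerate(frames):
            seeded = spec.with_seed(derive_pair_seed(seed, i, j))
            deg = degrade(clean, seeded)
            rest = restore(model, deg)
            ssim_r.append(ssim(rest, clean))
            psnr_r.append(psnr(rest, clean))
            ssim_d.append(ssim(deg, clean))
            psnr_d.append(psnr(deg, clean))
        family, level = describe_spec(spec)
        report.rows.append({
            "degradation_family": family,
            "level": level,
            "n_images": len(frames),
            "mean_ssim": float(np.mean(ssim_r)),
            "std_ssim": float(np.std(ssim_r)),
            "mean_psnr": float(np.mean(psnr_r)),
            "std_psnr": float(np.std(psnr_r)),
            "mean_ssim_degraded": float(np.mean(ssim_d)),
            "mean_psnr_degraded": float(np.mean(psnr_d)),
        })
    return report


def report_to_table(report: EvalReport, fmt: str = "csv",
                    path: str | Path | None = None) -> str:
    """Serialize a report as csv, markdown, or json (lossless for json)."""
    if fmt == "csv":
        text = report.to_frame().to_csv(index=False)
    elif fmt == "markdown":
        df = report.to_frame()
        header = "| " + " | ".join(df.columns) + " |"
        sep = "|" + "|".join(" --- " for _ in df.columns) + "|"
        lines = [header, sep]
        for _, row in df.iterrows():
            lines.append("| " + " | ".join(
                f"{v:.4f}" if isinstance(v, float) else str(v)
                for v in row.tolist()) + " |")
        text = "\n".join(lines) + "\n"
    elif fmt == "json":
        text = json.dumps({"metadata": report.metadata, "rows": report.rows},
                          indent=2)
    else:
        raise ParameterError(f"unknown format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def report_from_json(text: str) -> EvalReport:
    d = json.loads(text)
    return EvalReport(rows=d["rows"], metadata=d["metadata"])


def default_grid(include_cast: bool = True) -> list[DegradationSpec]:
    """The benchmark sweep: Gaussian sigma 10..60, one level each of
    speckle / salt-pepper / Poisson, and blur lengths {5, 9, 13} at angles
    {0, 45, 90, 135}."""
    cast = ColorCast(gains=(1.15, 1.0, 0.85), gamma=1.1) if include_cast else None
    grid: list[DegradationSpec] = []
    for sigma in (10, 20, 30, 40, 50, 60):
        grid.append(DegradationSpec(
            cast=cast, noise=NoiseSpec(family="gaussian", sigma=float(sigma))))
    grid.append(DegradationSpec(cast=cast, noise=NoiseSpec(family="speckle",
                                                           variance=0.05)))
    grid.append(DegradationSpec(cast=cast, noise=NoiseSpec(family="salt_pepper",
                                                           amount=0.05)))
    grid.append(DegradationSpec(cast=cast, noise=NoiseSpec(family="poisson",
                                                           peak=100.0)))
    for length in (5, 9, 13):
        for angle in (0.0, 45.0, 90.0, 135.0):
            grid.append(DegradationSpec(
                cast=cast, kernel=make_motion_kernel(length, angle)))
    return grid
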