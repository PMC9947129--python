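# endorestore

One-step restoration of endoscopic video frames: **denoising, motion
deblurring and white-balance correction in a single forward pass** of a
residual U-Net.

Minimally invasive surgery (knee arthroscopy in particular) produces
frames corrupted by sensor noise, motion blur from camera steering, and
strong color casts from un-white-balanced raw sensors under halogen or
LED illumination. Downstream vision tasks — tissue segmentation, tracking,
depth estimation — degrade sharply on such frames. Classical pipelines
chain separate denoisers, deblurring methods and color-constancy steps;
this package learns all three corrections jointly as one image-to-image
regression `y ≈ f(x, θ)`.

Because surgical ground truth is essentially impossible to capture
(no clean/blurred frame pairs exist inside a knee), the package is fully
self-contained: a seeded **tissue-phantom generator** produces clean
frames with the statistics of arthroscopic footage, a **degradation
simulator** corrupts them with

```
x = N( G * C(y) )        C: per-channel gain/gamma color cast
                         G: normalized motion-blur line kernel
                         N: Gaussian σ∈[10,60]/255, speckle,
                            salt-and-pepper, Poisson, or none
```

and the network is trained on the resulting pairs with a composite loss

```
L = w1·(1 − SSIM) + w2·max(0, (50 − PSNR)/50) + w3·MSE + w4·L_edge
```

in two stages: *coarse* (all degradation families, w=(1,1,1,0)) then
*fine* (blur subset only, with the Sobel edge-difference term, w=(1,1,1,1)),
both with Adam at learning rate 1e-4. The network is a depth-4 U-Net with
residual conv blocks, batch normalization, skip concatenation, and a
global input→output residual with a zero-initialized head, so the
untrained model is exactly the identity map. Everything — including the
reverse-mode autodiff, convolutions and Adam in `endorestore.nn` — runs on
numpy; there is no deep-learning framework dependency.

## Worked example

Train the desk-scale profile (≈200 synthetic 64×64 pairs, depth-2/base-8
network, 10 coarse + 5 fine epochs — a few minutes on one CPU) and score
it on held-out frames:

```python
from endorestore.experiments import run_tiny_experiment

r = run_tiny_experiment(seed=1, workdir="scratch/demo", sweep=True)
print(f"held-out @ Gaussian sigma=25: SSIM degraded {r.ssim_degraded:.3f}"
      f" -> restored {r.ssim_restored:.3f} (gain {r.ssim_gain:+.3f})")
print(f"edge loss on blurred frames: coarse {r.edge_loss_coarse_blur:.4f}"
      f" -> fine {r.edge_loss_fine_blur:.4f}")
for row in r.sweep.rows:
    print(f"  sigma={row['level']:.0f}  SSIM degraded"
          f" {row['mean_ssim_degraded']:.3f} -> restored {row['mean_ssim']:.3f}")
```

Output (seed 1):

```
held-out @ Gaussian sigma=25: SSIM degraded 0.146 -> restored 0.502 (gain +0.356)
edge loss on blurred frames: coarse 0.0481 -> fine 0.0430
  sigma=10  SSIM degraded 0.481 -> restored 0.844
  sigma=20  SSIM degraded 0.206 -> restored 0.647
  sigma=30  SSIM degraded 0.112 -> restored 0.411
  sigma=40  SSIM degraded 0.072 -> restored 0.236
  sigma=50  SSIM degraded 0.051 -> restored 0.141
  sigma=60  SSIM degraded 0.060 -> restored 0.095
```

Reading: restoration more than doubles held-out structural similarity at
σ=25; blur-subset fine-tuning with the edge term sharpens edges beyond the
coarse checkpoint; and restored quality falls monotonically with noise
level while always staying above the degraded baseline.

Shorter narrative scripts, one per capability, live in `examples/`
(phantom generation, degradation, metrics, training, evaluation). A thin
CLI wraps the same calls:

```bash
endorestore simulate --n 32 --size 64 --seed 0 --out frames/
endorestore degrade --in frames/ --out noisy/ --noise gaussian --sigma 25
endorestore train --config cfg.yaml --data frames/ --out model.npz
endorestore restore --checkpoint model.npz --in noisy/ --out restored/
endorestore evaluate --checkpoint model.npz --data frames/ --format csv
```

## Package layout

| module | contents |
| --- | --- |
| `endorestore.phantom` | seeded tissue-phantom generator, PNG datasets + manifests |
| `endorestore.degrade` | color cast, motion-blur kernels, five noise families |
| `endorestore.metrics` | MSE / PSNR / SSIM / edge loss + composite loss report |
| `endorestore.losses` | differentiable counterparts used in the training graph |
| `endorestore.model` | residual U-Net, checkpointing, `restore()` |
| `endorestore.training` | pairing, 70/15/15 splits, two-stage training loop |
| `endorestore.evaluation` | SSIM/PSNR sweeps over degradation grids, tables |
| `endorestore.experiments` | the fixed desk-scale profile used by tests/scripts |
| `endorestore.nn` | numpy autodiff, conv/BN/pool layers, Adam |
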