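# Methods

`endorestore` restores degraded endoscopic (arthroscopic) video frames in a
single forward pass: denoising, motion deblurring and white-balance
correction are learned jointly by one residual U-Net, trained entirely on
synthetic data produced by the package itself. This note records the model,
the synthetic-data assumptions, the numerical choices, and the limits of
what the shipped experiments demonstrate.

## Problem statement

A clean frame `y` is observed as

```
x = N( G * C(y) )
```

where `C` is a per-channel sensor color cast, `G` a motion-blur
point-spread function applied by convolution, and `N` one of five noise
processes (additive Gaussian with standard deviation σ quoted on the 0–255
scale, multiplicative speckle, salt-and-pepper, Poisson shot noise, or
none). All images live in `[0, 1]` as H×W×3 RGB arrays; every degradation
stage clips back into `[0, 1]`, because sensor saturation and underexposure
are part of the physics being modeled, not artifacts to avoid. Restoration
learns the inverse mapping `y ≈ f(x, θ)` as a direct image-to-image
regression.

## Degradation model

- **Color cast** `out_c = clip((in_c · gain_c)^γ)`. The cast emulates a raw,
  un-white-balanced sensor under a biased illuminant; it is analytically
  invertible wherever it did not clip, which the tests exploit as a
  round-trip oracle.
- **Motion blur**: an anti-aliased line of the requested length and angle is
  rasterized on an odd-sided grid through its center (weight falls off
  linearly with perpendicular distance, with a linear taper at the line
  ends), cropped to its non-zero bounding box, and normalized to unit sum.
  `length=1` is the exact identity kernel. Convolution uses edge-mirroring
  boundaries so frame borders are not darkened (a darkened border would
  teach the network a spurious vignette). Blur is uniform per frame;
  spatially varying blur fields are out of scope.
- **Noise**: Gaussian `σ/255` per pixel and channel; speckle
  `x·(1+N(0, v))`; salt-and-pepper corrupts a fraction `amount` of pixel
  *positions* (all three channels together, as a real dead/saturated sensor
  site would); Poisson draws `Pois(x·peak)/peak`, so `peak` — the expected
  photon count of a unit-intensity pixel — controls severity. Every draw is
  seeded and bit-reproducible.

The composition order cast → blur → noise follows the physical chain:
color response is scene-side, blur is optical, noise is added at the
sensor.

## Synthetic tissue phantoms

Clean/corrupted frame pairs cannot be captured inside a joint, and real
arthroscopy recordings are not redistributable, so training and evaluation
run on procedural "tissue phantoms" that emulate the *statistics* of arthroscopic footage rather
than its anatomy: smooth low-frequency intensity fields on a reddish tint
(Gaussian-filtered noise with correlation length `texture_scale`), a few
soft blobs, one or two sharp shading boundaries standing in for
meniscus/ligament edges, a multiplicative polynomial vignette around a
jittered optical center, warm (halogen-like, red-heavy) or cool
(LED-like, blue-heavy) illuminant gains, and a Poisson number of small
specular disks saturated to exactly 1.0. Per-frame brightness is drawn so
that frame means spread across roughly 0.2–0.8 instead of collapsing to
one operating point. Frames are pure functions of their config (Philox
counter-based streams, one sub-stream per frame index).

What the phantoms do **not** contain: real tissue texture, debris and
fluid motion, haze/smoke, lens distortion, specular *reflection geometry*,
temporal structure. Passing results therefore demonstrate that the
pipeline learns to invert its own degradation model on tissue-like
statistics — not clinical performance on real arthroscopy.

## Network

Depth-`d` U-Net whose conv pairs are residual blocks: two 3×3
convolution + batch-norm + ReLU stages plus an identity shortcut
(1×1-projected when the channel count changes). Encoder halves the
spatial dims (2×2 max-pool) and doubles the channels at each level;
decoder mirrors it with 2×2 transposed convolutions and skip
concatenation. Defaults: depth 4, base width 32 (32/64/128/256, bottleneck
512), 3×3 kernels, He-normal seeded initialization. Batch normalization
absorbs the very different input distributions the multi-level
degradations produce.

Two choices deserve justification:

- **Global residual skip.** The head is a zero-initialized 1×1 convolution
  whose output is *added to the input*, so the untrained network is exactly
  the identity map and training only has to learn the correction
  (DnCNN-style residual learning). Without it, a cold encoder–decoder must
  first learn to reproduce its input before it can improve on it; at the
  method's fixed learning rate of 1e-4 that burns thousands of optimizer
  steps and, at desk scale, held-out quality *drops* below the degraded
  input. The clipped final activation (`clip` to `[0, 1]`, gradients pass
  on the interior) pairs with the skip; a sigmoid head remains available
  for the non-residual variant.
- **Arbitrary frame sizes** are handled at inference by mirror-padding to
  the next multiple of `2^depth` and cropping the output, so the shape
  contract holds for any input ≥ 1 px.

The whole network, its reverse-mode autodiff, batch normalization and the
Adam optimizer are implemented on numpy inside `endorestore.nn`; the
backward pass of each convolution is an im2col matmul (full correlation
against the flipped, channel-transposed weights), verified against central
finite differences.

## Losses and metrics

The training objective is a weighted sum of four terms, each also exposed
as an evaluation metric:

- `L_SSIM = 1 − SSIM(pred, target)`, SSIM with the Wang et al. constants
  (11×11 Gaussian window, σ=1.5, K1=0.01, K2=0.03, population moments,
  dynamic range 1), computed per channel over fully valid window positions
  and averaged.
- `L_PSNR = max(0, (50 − PSNR)/50)`: PSNR is a maximand, so the loss uses
  its normalized deficit against a 50 dB reference — bounded, dimensionless
  and comparable in magnitude to the other terms. Reported PSNR is capped
  at 100 dB when the MSE underflows (below 1e-12) so identical images score
  finitely; under that convention a perfect prediction makes every term,
  and the total, exactly zero.
- `L_2`: plain pixel-space MSE. The "perceptual" reading of an L2 loss
  (feature-space distance under a pretrained network) is deliberately not
  the default: it would require downloaded weights and break
  self-containment.
- `L_edge`: mean absolute difference of Sobel gradient magnitudes computed
  on the channel-averaged luminance with edge-mirroring boundaries. Used
  only in the fine stage.

Differentiable counterparts of all four terms are built from the same
autodiff primitives (the SSIM window is applied as two separable 1-D
convolutions); they agree with the numpy metrics to ~1e-9 and carry small
epsilon guards (1e-12 inside the PSNR logarithm, a clamped-denominator
square root in the edge magnitude) so gradients stay finite at perfect
reconstructions.

## Training procedure

Stage 1 (**coarse**) optimizes SSIM+PSNR+L2 (weights 1,1,1,0) on pairs from
*all* degradation families; stage 2 (**fine**) continues on the
blur-containing subset only with the edge term enabled (1,1,1,1), so the
network concentrates on recovering sharp edges from blurred
representations. Adam at learning rate 1e-4 in both stages, optimizer
state reset between stages; running fine before coarse is rejected.
Training samples are random patches; each epoch passes once over every
(pair, transform) combination, where the transforms are the four
orientation-preserving dihedral symmetries (identity, horizontal flip,
vertical flip, 180° rotation) — the standard augmentation for patch-based
restoration. Splits are assigned 70/15/15 at the *clean-frame* level, so
every degraded version of a frame shares its split and held-out sets never
leak content. The checkpoint returned is the epoch with the best
validation SSIM. Everything (splits, shuffling, crops, init) is seeded;
a fixed seed reproduces the final parameters bit for bit.

## Desk-scale profile (`endorestore.experiments`)

One CPU cannot train the full model, so the package fixes a single tiny
profile used by the tests, the acceptance script and the examples:
29 phantom frames at 64×64 × 7 degradation specs (Gaussian σ=25, speckle
0.04, salt-and-pepper 0.05, Poisson peak 100, blurs of length 5/9 at
45°/90°, blur 7 at 0° + Gaussian σ=25) ≈ 200 pairs; a depth-2/base-8
network; 10 coarse epochs + 5 fine epochs, batch size 1, patch 64.
Batch 1 is deliberate: at a fixed learning rate Adam's movement is
proportional to the number of steps, and single-sample batches maximize
steps per epoch. Held-out improvement is measured at Gaussian σ=25 on the
test split with the coarse checkpoint; the fine/coarse comparison uses the
blur-only test pairs; the σ=10…60 sweep uses the final model. The profile
was fixed once, before the acceptance checks were frozen.

## Numerical conventions and degenerate inputs

- Motion-kernel weights below 1e-12 are zeroed before cropping so
  near-axis angles do not keep crumb columns alive.
- Kernel normalization is exact to 1e-9; `length=1` returns `[[1.0]]`.
- Noise with `family="none"` ignores all level parameters and copies.
- A degradation spec with no cast, no kernel and no noise is verified to
  be the byte-identical identity map.
- Phantom configs with `texture_scale=inf`, `n_blobs=0`,
  `vignette_strength=0`, `specular_density=0` produce a spatially constant
  frame (the degenerate corner of the generator).
- SSIM requires both image sides ≥ 11; smaller inputs raise a dimension
  error rather than silently shrinking the window (the differentiable
  version accepts an explicit window override for small-patch use).

## Known limitations

- Phantom realism, as above; no claim about real endoscopy transfers.
- Per-frame uniform blur; the real multi-motion, spatially varying case is
  not synthesized.
- The desk-scale network (depth 2, base 8) underfits heavy noise
  (σ ≥ 40): restored SSIM stays above the degraded baseline but absolute
  quality is low. The full-size configuration (depth 4, base 32) is
  implemented and tested for contracts, not trained at desk scale.
- Training on CPU in float32; results are reproducible per platform/BLAS
  but not guaranteed bit-identical across BLAS implementations.
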