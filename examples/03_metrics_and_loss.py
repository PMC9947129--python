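"""Score an image pair with the evaluation metrics and the composite loss.

The same four terms drive training (through their differentiable
counterparts) and evaluation: 1-SSIM, the PSNR deficit against 50 dB,
MSE, and the Sobel edge-magnitude difference.
"""

from endorestore import (DegradationSpec, LossWeights, NoiseSpec,
                         PhantomConfig, degrade, edge_loss, generate_phantom,
                         mse, psnr, ssim, total_loss)

clean = generate_phantom(PhantomConfig(seed=5, height=64, width=64))
noisy = degrade(clean, DegradationSpec(
    noise=NoiseSpec(family="gaussian", sigma=25.0, seed=1)))

print(f"SSIM      {ssim(noisy, clean):+.4f}   (1 = identical)")
print(f"PSNR      {psnr(noisy, clean):7.2f} dB")
print(f"MSE       {mse(noisy, clean):.6f}")
print(f"edge loss {edge_loss(noisy, clean):.6f}  (0 = identical gradients)")

rep = total_loss(noisy, clean, LossWeights.fine())
print(f"\ncomposite loss report: l_ssim={rep.l_ssim:.4f} "
      f"l_psnr={rep.l_psnr:.4f} l_2={rep.l_2:.6f} l_edge={rep.l_edge:.4f} "
      f"-> total {rep.total:.4f}")

perfect = total_loss(clean, clean, LossWeights.fine())
print(f"identical pair -> total {perfect.total} (exactly zero by convention)")
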