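"""Corrupt a clean frame with the full degradation chain.

Composition order mirrors the sensor physics: color cast (scene-side),
motion blur (optical), then noise (sensor-side); every stage clips to
[0, 1].
"""

from endorestore import (ColorCast, DegradationSpec, NoiseSpec, PhantomConfig,
                         degrade, generate_phantom, invert_color_cast,
                         make_motion_kernel, psnr, ssim)

clean = generate_phantom(PhantomConfig(seed=3, height=64, width=64))

spec = DegradationSpec(
    cast=ColorCast(gains=(1.2, 1.0, 0.8), gamma=1.1),   # raw, red-heavy sensor
    kernel=make_motion_kernel(length=7, angle=30.0),    # 7-px motion streak
    noise=NoiseSpec(family="gaussian", sigma=25.0, seed=0),
)
noisy = degrade(clean, spec)
print(f"degraded vs clean:  SSIM {ssim(noisy, clean):.3f}, "
      f"PSNR {psnr(noisy, clean):.2f} dB")
# low SSIM/PSNR: this is the input the restoration network sees

k = spec.kernel
print(f"blur kernel {k.grid.shape}, sum {k.grid.sum():.6f} (unit mass)")

# the color cast alone is analytically invertible (where it did not clip)
from endorestore import apply_color_cast
casted = apply_color_cast(clean * 0.6 + 0.2, spec.cast)
back = invert_color_cast(casted, spec.cast)
print(f"cast round-trip max error: {abs(back - (clean * 0.6 + 0.2)).max():.2e}")
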