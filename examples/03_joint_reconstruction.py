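"""Joint image + coil-sensitivity reconstruction from undersampled k-space.

Simulates a 4-coil acquisition of a synthetic phantom at 4x Cartesian
undersampling, reconstructs jointly with the diffusion prior, and compares
against the zero-filled baseline.
"""

import numpy as np

import pogmdm as pg

size = 64
phantom = pg.make_phantom(pg.PhantomSpec(shape=(size, size), seed=0))
coils = pg.make_coils(4, (size, size), seed=0)
mask = pg.make_mask("cartesian", size, size, acceleration=4.0,
                    acl_fraction=0.08, seed=0)
y, truth = pg.simulate_acquisition(phantom, coils, mask, sigma_n=0.01,
                                   rng=np.random.default_rng(0))
print(f"acquisition: 4 coils, {mask.e} of {size * size} frequencies "
      f"(acceleration {mask.achieved_acceleration:.1f})")

zf = pg.zero_filled_rss(y)
print(f"zero-filled RSS PSNR: {pg.psnr(zf, phantom):.2f} dB")

model = pg.desk_prior((size, size), seed=0)
sched = pg.DiffusionSchedule(steps=1000)
cfg = pg.ReconConfig(n_samples=4, seed=0)
mean, var, _ = pg.mmse_and_variance(y, mask, model, sched, cfg)
print(f"MMSE PSNR ({cfg.n_samples} samples): {pg.psnr(mean, phantom):.2f} dB")
print(f"SSIM {pg.ssim(mean, phantom):.3f}, "
      f"NMSE x100 {100 * pg.nmse(mean, phantom):.2f}")
print(f"mean pixel-wise variance on the anatomy: "
      f"{var[phantom > 0.1].mean():.2e}")
print("The gain over zero filling comes from the prior filling the "
      "unsampled frequencies while the coil sensitivities are estimated "
      "from the data; the variance map flags where samples disagree.")
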