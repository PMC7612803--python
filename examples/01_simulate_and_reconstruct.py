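"""Simulate a brain phantom and reconstruct it with MLEM, OSEM and MAP-EM.

Builds the desk-scale parallel-beam system, generates one piecewise-constant
phantom with lesions, Poisson-samples a low-count sinogram and compares the
classical reconstructions by NRMSE against the ground truth.
"""

import numpy as np

import fbsempet as fp
from fbsempet.phantoms import desk_counts

grid = fp.ImageGrid(32, 32)                      # 2.08 mm pixels
geom = fp.ScannerGeometry(48, 48)                # 48 angles x 48 radial bins
proj = fp.build_projector(grid, geom)
psf = fp.gaussian_psf(2.5, grid)                 # 2.5 mm FWHM image-space PSF
norm = fp.make_normalisation(geom, seed=1234)
sys6 = fp.assemble_system(proj, psf, np.ones(geom.n_bins), norm, 6, grid, geom)

ds = fp.build_dataset(1, 1, 1, sys6,
                      count_low=desk_counts(grid, 5e5),
                      count_high=desk_counts(grid, 1e8),
                      seed=0, geo_projector=proj)
s = ds["test"][0]
ref = s.activity.ravel() * s.scale_low           # ground truth on data scale
dm = s.activity.mean() * s.scale_low

mlem = fp.mlem_reconstruct(s.low.y, fp.SystemModel(
    core=s.sys.core, diag=s.sys.diag, subset_rows=[np.arange(s.sys.n_bins)],
    grid=grid, geom=geom), n_iters=12)
osem = fp.osem_reconstruct(s.low.y, s.sys, n_iters=2)        # 2 x 6 = 12 modules
mapem = fp.mapem_tikhonov(s.low.y, s.sys, beta=0.03, gamma=0.1, n_iters=2)

print(f"low-count sinogram total counts: {s.low.y.sum():.0f}")
print(f"MLEM   (12 full iterations) NRMSE: {fp.nrmse(mlem.final,  ref, dm):.4f}")
print(f"OSEM   (12 subset modules)  NRMSE: {fp.nrmse(osem.final,  ref, dm):.4f}")
print(f"MAP-EM (Tikhonov, beta=.03) NRMSE: {fp.nrmse(mapem.final, ref, dm):.4f}")
print("OSEM converges faster per module; the quadratic prior trades a little "
      "bias for lower noise.")
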