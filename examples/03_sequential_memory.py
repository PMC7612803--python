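"""The memory contract of sequential training.

Trains 12- and 60-module chains one module at a time and an end-to-end
60-module chain, and reports the peak number of array elements retained on
the autodiff tape: sequential training retains one module's activations
regardless of chain depth, end-to-end retains all of them.
"""

import numpy as np

import fbsempet as fp
from fbsempet import autodiff as ad
from fbsempet.fbsem_net import FBSEMConfig, ModuleChain
from fbsempet.phantoms import desk_counts
from fbsempet.training import (TrainingConfig, build_iteration_targets,
                               train_end_to_end, train_sequential)

grid = fp.ImageGrid(32, 32)
geom = fp.ScannerGeometry(48, 48)
proj = fp.build_projector(grid, geom)
sys6 = fp.assemble_system(proj, fp.gaussian_psf(2.5, grid),
                          np.ones(geom.n_bins),
                          fp.make_normalisation(geom, seed=1234), 6, grid, geom)
ds = fp.build_dataset(2, 1, 1, sys6, count_low=desk_counts(grid, 5e5),
                      count_high=desk_counts(grid, 1e8), seed=3,
                      geo_projector=proj)


def run(n_iters, regime):
    for s in ds["train"]:
        build_iteration_targets(s, n_iters=n_iters, n_subsets=6)
    chain = ModuleChain(FBSEMConfig(n_iters=n_iters, n_subsets=6,
                                    n_channels=4), seed=0)
    tc = TrainingConfig(lr=0.01, epochs=1, batch_size=2, regime=regime,
                        seed=0, epochs_per_module=1)
    ad.ledger.reset()
    if regime == "sequential_IS":
        train_sequential(ds["train"], chain, tc)
    else:
        train_end_to_end(ds["train"], chain, tc)
    return ad.ledger.peak


p12 = run(2, "sequential_IS")
p60 = run(10, "sequential_IS")
e2e = run(10, "end_to_end_final")
print(f"peak retained elements, sequential 12 modules: {p12:>12,}")
print(f"peak retained elements, sequential 60 modules: {p60:>12,}")
print(f"peak retained elements, end-to-end 60 modules: {e2e:>12,}")
print(f"sequential / end-to-end: {p60 / e2e:.4f} "
      f"(a {100 * (1 - p60 / e2e):.1f}% reduction; independent of depth)")
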