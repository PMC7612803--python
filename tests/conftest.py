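"""Shared desk-scale fixtures: a 32x32 parallel-beam system and a small
synthetic dataset with iteration-dependent targets (12 modules)."""

import numpy as np
import pytest

import fbsempet as fp
from fbsempet.phantoms import desk_counts
from fbsempet.training import build_iteration_targets

NORM_SEED = 1234


@pytest.fixture(scope="session")
def small_setup():
    grid = fp.ImageGrid(32, 32)
    geom = fp.ScannerGeometry(48, 48)
    proj = fp.build_projector(grid, geom)
    psf = fp.gaussian_psf(2.5, grid)
    norm = fp.make_normalisation(geom, seed=NORM_SEED)
    return grid, geom, proj, psf, norm


@pytest.fixture(scope="session")
def small_system(small_setup):
    """Template system (normalisation only in the diag), 6 angular subsets."""
    grid, geom, proj, psf, norm = small_setup
    return fp.assemble_system(proj, psf, np.ones(geom.n_bins), norm, 6, grid, geom)


@pytest.fixture(scope="session")
def small_system_1sub(small_setup):
    grid, geom, proj, psf, norm = small_setup
    return fp.assemble_system(proj, psf, np.ones(geom.n_bins), norm, 1, grid, geom)


@pytest.fixture(scope="session")
def counts_small(small_setup):
    grid = small_setup[0]
    return desk_counts(grid, 5e5), desk_counts(grid, 1e8)


@pytest.fixture(scope="session")
def tiny_dataset(small_setup, small_system, counts_small):
    """16/4/4 split with 12-module iteration-dependent targets."""
    proj = small_setup[2]
    cl, ch = counts_small
    ds = fp.build_dataset(16, 4, 4, small_system, count_low=cl, count_high=ch,
                          seed=1, geo_projector=proj)
    for s in ds["train"] + ds["val"] + ds["test"]:
        build_iteration_targets(s, n_iters=2, n_subsets=6)
    return ds


@pytest.fixture(scope="session")
def one_sample(small_setup, small_system, counts_small):
    """A single phantom with its per-sample system and low-count data."""
    grid, geom, proj, psf, norm = small_setup
    cl, ch = counts_small
    ds = fp.build_dataset(1, 1, 1, small_system, count_low=cl, count_high=ch,
                          seed=7, geo_projector=proj)
    return ds["train"][0]


@pytest.fixture(scope="session")
def toy_system():
    """An 8x8 toy for dense-oracle comparisons."""
    grid = fp.ImageGrid(8, 8)
    geom = fp.ScannerGeometry(6, 10)
    proj = fp.build_projector(grid, geom)
    psf = fp.gaussian_psf(0.0, grid)
    sys = fp.assemble_system(proj, psf, np.ones(geom.n_bins),
                             np.ones(geom.n_bins), 2, grid, geom)
    return sys
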