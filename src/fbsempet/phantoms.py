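"""Procedural brain-like phantoms and synthetic dataset generation.

Piecewise-constant 2D (optionally 3D) activity images built from nested
ellipses — skin ring, skull ring, CSF rim, a grey-matter ribbon obtained by
morphological erosion of the brain mask, and a white-matter core — with
circular hot lesions of 2-8 mm radius.  Attenuation maps take exactly the
values {0, 0.0975, 0.13} cm^-1 (air / soft tissue / skull).  Each dataset
sample pairs a low-count Poisson-sampled sinogram with the noise-free
high-count mean sinogram used for target reconstruction.

The training intensity distribution is GM 96 +- 5, WM 32 +- 5 (a 3:1 ratio
in expectation), skin 16, CSF and skull 0; alternative test distributions
shift the GM/WM/skin means to probe generalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import h5py
import numpy as np
from scipy import ndimage

from .sysmodel import (ImageGrid, SinogramSet, SystemModel,
                       attenuation_factors, sample_poisson, scale_to_counts)

# region labels
AIR, SKIN, SKULL, CSF, GM, WM, LESION = 0, 1, 2, 3, 4, 5, 6

MU_SKULL = 0.13    # cm^-1
MU_TISSUE = 0.0975
MU_AIR = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    """Region intensity statistics and lesion parameters."""

    gm_mean: float = 96.0
    wm_mean: float = 32.0
    skin_value: float = 16.0
    csf_value: float = 0.0
    skull_value: float = 0.0
    intensity_sd: float = 5.0
    lesion_radius_mm: tuple = (2.0, 8.0)
    lesion_contrast: float = 1.3       # x the sample's GM value
    n_lesions_range: tuple = (1, 3)

    def __post_init__(self):
        if min(self.gm_mean, self.wm_mean, self.skin_value,
               self.csf_value, self.skull_value) < 0:
            raise ValueError("region means must be nonnegative")
        lo, hi = self.lesion_radius_mm
        if not (2.0 <= lo <= hi <= 8.0):
            raise ValueError("lesion radius range must lie within [2, 8] mm")


def distribution_variant(spec: PhantomSpec, name: str) -> PhantomSpec:
    """Intensity variants used to probe generalisation to shifted uptake."""
    tables = {
        "train": dict(wm_mean=32.0, gm_mean=96.0, skin_value=16.0),
        "test1": dict(wm_mean=64.0, gm_mean=80.0, skin_value=32.0),
        "test2": dict(wm_mean=5.0, gm_mean=120.0, skin_value=32.0),
    }
    if name not in tables:
        raise ValueError(f"unknown distribution variant: {name!r}")
    return replace(spec, **tables[name])


def _ellipse_mask(grid: ImageGrid, center, semi_axes, angle: float,
                  scale: float) -> np.ndarray:
    """Boolean mask of the (rotated, scaled) ellipse/ellipsoid interior."""
    if grid.nz is None:
        yy, xx = np.meshgrid(np.arange(grid.ny), np.arange(grid.nx), indexing="ij")
        x = xx - center[0]
        y = yy - center[1]
        c, s = np.cos(angle), np.sin(angle)
        xr = c * x + s * y
        yr = -s * x + c * y
        return (xr / (scale * semi_axes[0])) ** 2 + (yr / (scale * semi_axes[1])) ** 2 <= 1.0
    zz, yy, xx = np.meshgrid(np.arange(grid.nz), np.arange(grid.ny),
                             np.arange(grid.nx), indexing="ij")
    x = xx - center[0]
    y = yy - center[1]
    z = zz - center[2]
    c, s = np.cos(angle), np.sin(angle)
    xr = c * x + s * y
    yr = -s * x + c * y
    return ((xr / (scale * semi_axes[0])) ** 2
            + (yr / (scale * semi_axes[1])) ** 2
            + (z / (scale * semi_axes[2])) ** 2) <= 1.0


def make_brain_phantom(grid: ImageGrid, spec: PhantomSpec, seed: int):
    """One piecewise-constant phantom: (activity, mu map, label map).

    Nested ellipses with random eccentricity and rotation under `seed`;
    region uptake values are drawn normal(mean, sd) truncated at zero for
    GM and WM so the activity is constant within each label.
    """
    if min(grid.nx, grid.ny) < 24:
        raise ValueError("grid too small for the nested-ring anatomy")
    rng = np.random.default_rng(seed)
    if grid.nz is None:
        center = [(grid.nx - 1) / 2 + rng.uniform(-1, 1),
                  (grid.ny - 1) / 2 + rng.uniform(-1, 1)]
        semi = [0.45 * grid.nx * rng.uniform(0.88, 1.0),
                0.45 * grid.ny * rng.uniform(0.78, 0.95)]
    else:
        center = [(grid.nx - 1) / 2 + rng.uniform(-1, 1),
                  (grid.ny - 1) / 2 + rng.uniform(-1, 1),
                  (grid.nz - 1) / 2]
        semi = [0.45 * grid.nx * rng.uniform(0.88, 1.0),
                0.45 * grid.ny * rng.uniform(0.78, 0.95),
                0.45 * grid.nz * rng.uniform(0.85, 1.0)]
    angle = rng.uniform(0, np.pi)

    outer = _ellipse_mask(grid, center, semi, angle, 1.0)
    skull_o = _ellipse_mask(grid, center, semi, angle, 0.92)
    csf_o = _ellipse_mask(grid, center, semi, angle, 0.84)
    brain = _ellipse_mask(grid, center, semi, angle, 0.77)

    labels = np.full(grid.shape, AIR, dtype=np.int16)
    labels[outer & ~skull_o] = SKIN
    labels[skull_o & ~csf_o] = SKULL
    labels[csf_o & ~brain] = CSF
    ribbon_px = max(2, int(round(6.0 / grid.pixel_size_mm)))
    wm_core = ndimage.binary_erosion(brain, iterations=ribbon_px)
    labels[brain & ~wm_core] = GM
    labels[wm_core] = WM
    for lab in (SKIN, SKULL, CSF, GM, WM):
        if not np.any(labels == lab):
            raise ValueError("grid too small: a ring region came out empty")

    gm_val = max(0.0, rng.normal(spec.gm_mean, spec.intensity_sd))
    wm_val = max(0.0, rng.normal(spec.wm_mean, spec.intensity_sd))
    activity = np.zeros(grid.shape)
    activity[labels == SKIN] = spec.skin_value
    activity[labels == CSF] = spec.csf_value
    activity[labels == SKULL] = spec.skull_value
    activity[labels == GM] = gm_val
    activity[labels == WM] = wm_val

    mu = np.zeros(grid.shape)
    mu[labels != AIR] = MU_TISSUE
    mu[labels == SKULL] = MU_SKULL
    return activity, mu, labels


def insert_lesions(activity: np.ndarray, labels: np.ndarray, n_lesions: int,
                   seed: int, grid: ImageGrid, spec: PhantomSpec):
    """Insert circular hot lesions into GM/WM; returns (activity, labels).

    Centres are uniform over the brain interior, radii uniform in the spec's
    mm range, intensity = lesion_contrast x the sample's GM value; disks are
    clipped by the brain mask.  Labels gain the LESION region so the image
    stays piecewise constant over the label map.
    """
    if n_lesions < 0:
        raise ValueError("n_lesions must be >= 0")
    activity = activity.copy()
    labels = labels.copy()
    if n_lesions == 0:
        return activity, labels
    rng = np.random.default_rng(seed)
    brain = (labels == GM) | (labels == WM)
    if not np.any(brain):
        raise ValueError("empty brain interior")
    gm_val = float(activity[labels == GM].mean())
    lesion_val = spec.lesion_contrast * gm_val
    coords = np.argwhere(brain)
    axes = np.meshgrid(*[np.arange(s) for s in grid.shape], indexing="ij")
    for _ in range(n_lesions):
        c = coords[rng.integers(len(coords))]
        r_mm = rng.uniform(*spec.lesion_radius_mm)
        r_px = r_mm / grid.pixel_size_mm
        d2 = sum((ax - ci) ** 2 for ax, ci in zip(axes, c))
        disk = (d2 <= r_px ** 2) & brain
        activity[disk] = lesion_val
        labels[disk] = LESION
    return activity, labels


@dataclass
class DatasetSample:
    """One phantom with its sinogram data and (optionally) OSEM targets."""

    activity: np.ndarray
    mu: np.ndarray
    labels: np.ndarray
    sys: SystemModel
    low: SinogramSet
    high: SinogramSet
    scale_low: float
    scale_high: float
    seed: int
    targets: object = None   # filled by training.build_iteration_targets

    @property
    def brain_mask(self) -> np.ndarray:
        return self.activity > 0


def rotation_augment(activity: np.ndarray, mu: np.ndarray,
                     labels: np.ndarray, n: int, seed: int,
                     max_deg: float = 10.0):
    """`n` randomly rotated copies (axial, angles uniform in [0, max_deg]).

    Activity and mu are rotated with linear interpolation (values clipped at
    zero), labels with nearest-neighbour.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        ang = rng.uniform(0.0, max_deg)
        kw = dict(angle=ang, reshape=False, mode="constant", cval=0.0)
        if activity.ndim == 3:
            kw["axes"] = (1, 2)
        out.append((np.maximum(ndimage.rotate(activity, order=1, **kw), 0.0),
                    np.maximum(ndimage.rotate(mu, order=1, **kw), 0.0),
                    ndimage.rotate(labels, order=0, **kw)))
    return out


def build_dataset(n_train: int, n_val: int, n_test: int, sys: SystemModel,
                  count_low: float = 5e5, count_high: float = 1e8,
                  seed: int = 0, spec: PhantomSpec | None = None,
                  geo_projector=None, n_rotations: int = 0) -> dict:
    """Generate disjointly-seeded train/val/test splits.

    `sys` is a template system model whose diag holds normalisation only;
    each sample gets its own attenuation factors from its mu map (computed
    with `geo_projector`, the PSF-free geometric projector — defaults to the
    template's core).  The low-count sinogram is a Poisson sample of the
    mean scaled to `count_low`; the high-count set carries the noise-free
    mean scaled to `count_high`.  With `n_rotations > 0`, each training
    sample additionally appears in that many randomly rotated copies
    (angles within [0, 10] degrees).
    """
    for n in (n_train, n_val, n_test):
        if n < 1:
            raise ValueError("each split needs at least one sample")
    if count_low <= 0 or count_high <= 0:
        raise ValueError("count levels must be positive")
    spec = spec or PhantomSpec()
    proj = geo_projector if geo_projector is not None else sys.core
    rng = np.random.default_rng(seed)
    splits = {"train": n_train, "val": n_val, "test": n_test}
    out = {}
    for split, n in splits.items():
        samples = []
        for _ in range(n):
            s_phan, s_les, s_noise = rng.integers(0, 2 ** 31 - 1, size=3)
            activity, mu, labels = make_brain_phantom(sys.grid, spec, int(s_phan))
            n_les = int(rng.integers(spec.n_lesions_range[0],
                                     spec.n_lesions_range[1] + 1))
            activity, labels = insert_lesions(activity, labels, n_les,
                                              int(s_les), sys.grid, spec)
            variants = [(activity, mu, labels)]
            if n_rotations > 0 and split == "train":
                s_rot = int(rng.integers(0, 2 ** 31 - 1))
                variants += rotation_augment(activity, mu, labels,
                                             n_rotations, s_rot)
            for act_v, mu_v, lab_v in variants:
                a = attenuation_factors(mu_v, proj)
                sys_s = sys.with_diag(sys.diag * a)
                ybar = sys_s.forward(act_v)
                high_ybar, f_high = scale_to_counts(ybar, count_high)
                low_ybar, f_low = scale_to_counts(ybar, count_low)
                y_low = sample_poisson(low_ybar, int(s_noise))
                samples.append(DatasetSample(
                    activity=act_v, mu=mu_v, labels=lab_v, sys=sys_s,
                    low=SinogramSet(y=y_low, ybar=low_ybar),
                    high=SinogramSet(y=high_ybar, ybar=high_ybar),
                    scale_low=f_low, scale_high=f_high, seed=int(s_phan)))
        out[split] = samples
    return out


#: image side length of the full-scale 2D acquisition protocol the count
#: levels (500k low / 100M high) refer to
REFERENCE_IMAGE_SIDE = 172


def desk_counts(grid: ImageGrid, level: float) -> float:
    """Count level for a desk-scale grid preserving count density.

    The quoted total count levels belong to a 172x172 reconstruction; what
    controls both the reconstruction noise and the EM operating point is the
    count density (counts per pixel), so desk-scale studies scale the totals
    by n_pixels / 172^2 (e.g. 500k becomes ~17.3k on a 32x32 grid).
    """
    return level * grid.n_voxels / REFERENCE_IMAGE_SIDE ** 2


def save_dataset(path: str, dataset: dict):
    """Store a dataset as one HDF5 file (system cores are not duplicated)."""
    with h5py.File(path, "w") as f:
        for split, samples in dataset.items():
            g = f.create_group(split)
            for i, s in enumerate(samples):
                gi = g.create_group(str(i))
                gi.create_dataset("activity", data=s.activity)
                gi.create_dataset("mu", data=s.mu)
                gi.create_dataset("labels", data=s.labels)
                gi.create_dataset("diag", data=s.sys.diag)
                s.low.to_hdf5(gi.create_group("low"))
                s.high.to_hdf5(gi.create_group("high"))
                gi.attrs["scale_low"] = s.scale_low
                gi.attrs["scale_high"] = s.scale_high
                gi.attrs["seed"] = s.seed


def load_dataset(path: str, sys: SystemModel) -> dict:
    """Load a dataset saved by :func:`save_dataset`, rebinding to `sys`'s core."""
    out = {}
    with h5py.File(path, "r") as f:
        for split in f:
            samples = []
            g = f[split]
            for i in sorted(g, key=int):
                gi = g[i]
                samples.append(DatasetSample(
                    activity=gi["activity"][:], mu=gi["mu"][:],
                    labels=gi["labels"][:],
                    sys=sys.with_diag(gi["diag"][:]),
                    low=SinogramSet.from_hdf5(gi["low"]),
                    high=SinogramSet.from_hdf5(gi["high"]),
                    scale_low=float(gi.attrs["scale_low"]),
                    scale_high=float(gi.attrs["scale_high"]),
                    seed=int(gi.attrs["seed"])))
            out[split] = samples
    return out


def export_nifti(volume: np.ndarray, grid: ImageGrid, path: str):
    """Write a 3D volume as NIfTI (RAS, voxel sizes from the grid)."""
    import nibabel as nib

    vz = 2.03 if grid.nz is not None else grid.pixel_size_mm
    affine = np.diag([grid.pixel_size_mm, grid.pixel_size_mm, vz, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), path)
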