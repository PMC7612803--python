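"""Affine Poisson forward model for 2D parallel-beam emission tomography.

The measured sinogram counts y are modelled as Poisson draws with mean

    ybar = P x + r + s

where P is the system matrix (geometric projector composed with an
image-space Gaussian PSF and per-bin attenuation/normalisation factors),
x the nonnegative activity image, and r, s the mean randoms and scatters
(carried as zero vectors by default).  The geometry is a configurable
desk-scale parallel-beam stand-in: an exact sparse matrix so the adjoint
used by EM is exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
EPS_DIV = 1e-12  # floor for denominators in EM-style ratios


@dataclass(frozen=True)
class ImageGrid:
    """Reconstruction grid; pixels are square, sizes in mm."""

    nx: int
    ny: int
    nz: int | None = None
    pixel_size_mm: float = 2.08

    def __post_init__(self):
        dims = [self.nx, self.ny] + ([self.nz] if self.nz is not None else [])
        if any(d < 8 for d in dims):
            raise ValueError("all grid dimensions must be >= 8")
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")

    @property
    def n_voxels(self) -> int:
        n = self.nx * self.ny
        return n * self.nz if self.nz is not None else n

    @property
    def shape(self) -> tuple:
        return (self.ny, self.nx) if self.nz is None else (self.nz, self.ny, self.nx)


@dataclass(frozen=True)
class ScannerGeometry:
    """Parallel-beam geometry: uniformly spaced view angles in [0, pi)."""

    n_angles: int
    n_radial_bins: int

    def __post_init__(self):
        if self.n_angles < 2:
            raise ValueError("need at least 2 projection angles")
        if self.n_radial_bins < 1:
            raise ValueError("need at least 1 radial bin")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    @property
    def n_bins(self) -> int:
        return self.n_angles * self.n_radial_bins


def build_projector(grid: ImageGrid, geom: ScannerGeometry) -> sp.csr_matrix:
    """Geometric projector: line integrals by ray sampling with bilinear
    interpolation (step 0.5 pixel); weights carry the mm path-length scale.

    Returns a sparse (n_angles*n_radial_bins) x (ny*nx) matrix; sinogram rows
    are ordered angle-major (all radial bins of angle 0 first).
    """
    if grid.nz is not None:
        raise ValueError("projector is 2D; use slice-by-slice application for 3D")
    px = grid.pixel_size_mm
    nx, ny = grid.nx, grid.ny
    nb = geom.n_radial_bins
    # radial offsets at pixel pitch, centred on the grid centre
    r_off = (np.arange(nb) - (nb - 1) / 2.0) * px
    half_diag = 0.5 * px * float(np.hypot(nx, ny)) + px
    step = 0.5 * px
    nt = int(np.ceil(2 * half_diag / step))
    t = (np.arange(nt) + 0.5) * step - half_diag
    blocks = []
    N = nx * ny
    for theta in geom.angles:
        u = np.array([np.cos(theta), np.sin(theta)])
        v = np.array([-np.sin(theta), np.cos(theta)])
        # sample points: (nb, nt, 2)
        pts = r_off[:, None, None] * u[None, None, :] + t[None, :, None] * v[None, None, :]
        fx = pts[..., 0] / px + (nx - 1) / 2.0
        fy = pts[..., 1] / px + (ny - 1) / 2.0
        ix0 = np.floor(fx).astype(np.int64)
        iy0 = np.floor(fy).astype(np.int64)
        dx = fx - ix0
        dy = fy - iy0
        rows_idx = np.broadcast_to(np.arange(nb)[:, None], fx.shape)
        rr, cc, vv = [], [], []
        for ox, oy, w in (
            (0, 0, (1 - dx) * (1 - dy)),
            (1, 0, dx * (1 - dy)),
            (0, 1, (1 - dx) * dy),
            (1, 1, dx * dy),
        ):
            ix = ix0 + ox
            iy = iy0 + oy
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny) & (w > 0)
            rr.append(rows_idx[ok])
            cc.append((iy[ok] * nx + ix[ok]))
            vv.append(w[ok] * step)
        block = sp.coo_matrix(
            (np.concatenate(vv), (np.concatenate(rr), np.concatenate(cc))),
            shape=(nb, N),
        )
        blocks.append(block.tocsr())
    return sp.vstack(blocks, format="csr")


def _blur_matrix_1d(n: int, sigma_px: float) -> sp.csr_matrix:
    """Column-normalised discrete Gaussian: mass-preserving at the edges."""
    if sigma_px <= 0:
        return sp.identity(n, format="csr")
    rad = max(1, int(np.ceil(4 * sigma_px)))
    i = np.arange(n)
    cols, rows, vals = [], [], []
    offs = np.arange(-rad, rad + 1)
    w = np.exp(-0.5 * (offs / sigma_px) ** 2)
    for j in range(n):
        ii = j + offs
        ok = (ii >= 0) & (ii < n)
        wj = w[ok]
        wj = wj / wj.sum()
        rows.append(ii[ok])
        cols.append(np.full(ok.sum(), j))
        vals.append(wj)
    return sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()


def gaussian_psf(fwhm_mm: float, grid: ImageGrid) -> sp.csr_matrix:
    """Image-space Gaussian blur as a sparse (N x N) operator.

    sigma = fwhm / (2 sqrt(2 ln 2)) converted to pixels; the kernel columns
    are renormalised at the edges so any nonnegative image keeps its total.
    fwhm_mm = 0 returns the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    sigma_px = fwhm_mm * FWHM_TO_SIGMA / grid.pixel_size_mm
    bx = _blur_matrix_1d(grid.nx, sigma_px)
    by = _blur_matrix_1d(grid.ny, sigma_px)
    # row-major flattening of (ny, nx): operator = kron(By, Bx)
    return sp.kron(by, bx, format="csr")


def attenuation_factors(mu: np.ndarray, projector: sp.spmatrix) -> np.ndarray:
    """Survival probabilities a_i = exp(-integral of mu along line i).

    mu is in cm^-1 on the image grid; the projector produces line integrals
    in value*mm, hence the /10 conversion.
    """
    mu = np.asarray(mu, dtype=np.float64)
    if np.any(mu < 0):
        raise ValueError("attenuation map must be nonnegative")
    line_int_mm = projector @ mu.ravel()
    return np.exp(-line_int_mm / 10.0)


@dataclass
class SystemModel:
    """Effective system matrix P = diag(a*n) @ P_geo @ H_psf with subsets.

    ``core`` is the shared geometric+PSF part; ``diag`` carries the
    per-sinogram-bin attenuation*normalisation factors (this is the only
    per-phantom piece, so many system models can share one ``core``).
    """

    core: sp.csr_matrix
    diag: np.ndarray
    subset_rows: list[np.ndarray]
    grid: ImageGrid
    geom: ScannerGeometry
    _sub_csr: list = field(default_factory=list, repr=False)
    _sub_csr_T: list = field(default_factory=list, repr=False)
    subset_sens: np.ndarray | None = None
    sens: np.ndarray | None = None

    def __post_init__(self):
        if not self._sub_csr:
            self._sub_csr = [self.core[rows] for rows in self.subset_rows]
            self._sub_csr_T = [A.T.tocsr() for A in self._sub_csr]
        if self.subset_sens is None:
            self.subset_sens = np.stack(
                [At @ self.diag[rows]
                 for At, rows in zip(self._sub_csr_T, self.subset_rows)]
            )
            self.sens = self.subset_sens.sum(axis=0)

    @property
    def n_subsets(self) -> int:
        return len(self.subset_rows)

    @property
    def n_bins(self) -> int:
        return self.core.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.core.shape[1]

    @property
    def P(self) -> sp.csr_matrix:
        """Effective system matrix as an explicit sparse matrix."""
        return sp.diags(self.diag) @ self.core

    def forward(self, x, r=0.0, s_sc=0.0):
        """ybar = P x + r + s; x may be an image or flat vector."""
        return self.diag * (self.core @ np.asarray(x, dtype=np.float64).ravel()) + r + s_sc

    def back(self, v):
        return self.core.T @ (self.diag * np.asarray(v, dtype=np.float64))

    def forward_subset(self, m: int, x):
        rows = self.subset_rows[m]
        return self.diag[rows] * (self._sub_csr[m] @ np.asarray(x).ravel())

    def back_subset(self, m: int, v):
        rows = self.subset_rows[m]
        return self._sub_csr_T[m] @ (self.diag[rows] * np.asarray(v))

    def with_diag(self, diag: np.ndarray) -> "SystemModel":
        """A system sharing this core but with new attenuation/normalisation."""
        return SystemModel(core=self.core, diag=np.asarray(diag, dtype=np.float64),
                           subset_rows=self.subset_rows, grid=self.grid, geom=self.geom,
                           _sub_csr=self._sub_csr, _sub_csr_T=self._sub_csr_T,
                           subset_sens=None, sens=None)

    # -- serialisation -------------------------------------------------------
    def to_hdf5(self, path: str):
        with h5py.File(path, "w") as f:
            f.create_dataset("core_data", data=self.core.data)
            f.create_dataset("core_indices", data=self.core.indices)
            f.create_dataset("core_indptr", data=self.core.indptr)
            f.attrs["core_shape"] = self.core.shape
            f.create_dataset("diag", data=self.diag)
            f.create_dataset("sensitivity", data=self.sens)
            for m, rows in enumerate(self.subset_rows):
                f.create_dataset(f"subset_indices/{m}", data=rows)
            f.attrs["grid"] = (self.grid.nx, self.grid.ny, self.grid.pixel_size_mm)
            f.attrs["geom"] = (self.geom.n_angles, self.geom.n_radial_bins)

    @classmethod
    def from_hdf5(cls, path: str) -> "SystemModel":
        with h5py.File(path, "r") as f:
            core = sp.csr_matrix(
                (f["core_data"][:], f["core_indices"][:], f["core_indptr"][:]),
                shape=tuple(f.attrs["core_shape"]),
            )
            diag = f["diag"][:]
            n_sub = len(f["subset_indices"])
            rows = [f[f"subset_indices/{m}"][:] for m in range(n_sub)]
            gx, gy, px = f.attrs["grid"]
            na, nb = f.attrs["geom"]
        return cls(core=core, diag=diag, subset_rows=rows,
                   grid=ImageGrid(int(gx), int(gy), pixel_size_mm=float(px)),
                   geom=ScannerGeometry(int(na), int(nb)))


def make_normalisation(geom: ScannerGeometry, seed: int | None = None,
                       enabled: bool = True) -> np.ndarray:
    """Per-bin detection efficiencies, uniform in [0.8, 1.2] under `seed`."""
    if not enabled or seed is None:
        return np.ones(geom.n_bins)
    rng = np.random.default_rng(seed)
    return rng.uniform(0.8, 1.2, size=geom.n_bins)


def assemble_system(projector: sp.spmatrix, psf: sp.spmatrix,
                    atten: np.ndarray, norm: np.ndarray, n_subsets: int,
                    grid: ImageGrid, geom: ScannerGeometry) -> SystemModel:
    """Compose the effective system matrix and its angular subsets.

    Subsets are assigned round-robin over projection angles (angle k goes to
    subset k mod n_subsets); per-subset sensitivity images are precomputed.
    """
    if n_subsets > geom.n_angles:
        raise ValueError("n_subsets cannot exceed n_angles")
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    core = (projector @ psf).tocsr()
    diag = np.asarray(atten, dtype=np.float64) * np.asarray(norm, dtype=np.float64)
    nb = geom.n_radial_bins
    subset_rows = []
    for m in range(n_subsets):
        angles = np.arange(m, geom.n_angles, n_subsets)
        rows = (angles[:, None] * nb + np.arange(nb)[None, :]).ravel()
        subset_rows.append(np.sort(rows))
    return SystemModel(core=core, diag=diag, subset_rows=subset_rows,
                       grid=grid, geom=geom)


@dataclass
class SinogramSet:
    """Measured counts y, their mean ybar, and mean randoms/scatters."""

    y: np.ndarray
    ybar: np.ndarray
    r: np.ndarray | None = None
    s_sc: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        self.ybar = np.asarray(self.ybar, dtype=np.float64)
        M = self.y.shape[0]
        if self.r is None:
            self.r = np.zeros(M)
        if self.s_sc is None:
            self.s_sc = np.zeros(M)
        for name, v in (("ybar", self.ybar), ("r", self.r), ("s_sc", self.s_sc)):
            if v.shape[0] != M:
                raise ValueError(f"{name} length mismatch")
            if np.any(v < 0):
                raise ValueError(f"{name} must be nonnegative")
        if np.any(self.y < 0):
            raise ValueError("counts must be nonnegative")

    def to_hdf5(self, group):
        for name, v in (("y", self.y), ("ybar", self.ybar),
                        ("r", self.r), ("s", self.s_sc)):
            group.create_dataset(name, data=v)

    @classmethod
    def from_hdf5(cls, group) -> "SinogramSet":
        return cls(y=group["y"][:], ybar=group["ybar"][:],
                   r=group["r"][:], s_sc=group["s"][:])


def forward_model(x: np.ndarray, sys: SystemModel,
                  r=0.0, s_sc=0.0) -> np.ndarray:
    """ybar = P x + r + s for a nonnegative activity image."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("activity must be nonnegative")
    if x.size != sys.n_voxels:
        raise ValueError("image size does not match the system matrix")
    return sys.forward(x, r=r, s_sc=s_sc)


def scale_to_counts(ybar: np.ndarray, total_counts: float):
    """Rescale a mean sinogram to a prescribed total count level.

    Returns (scaled ybar, scale factor) so one phantom can supply both the
    low-count measurement and the high-count target data.
    """
    ybar = np.asarray(ybar, dtype=np.float64)
    tot = ybar.sum()
    if tot <= 0:
        raise ValueError("cannot scale an all-zero sinogram")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    factor = total_counts / tot
    return ybar * factor, factor


def sample_poisson(ybar: np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draws y_i ~ Poisson(ybar_i), reproducible by seed."""
    ybar = np.asarray(ybar, dtype=np.float64)
    if np.any(ybar < 0):
        raise ValueError("Poisson means must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(ybar).astype(np.float64)
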