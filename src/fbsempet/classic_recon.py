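"""Classical Poisson reconstruction: MLEM, OSEM, MAP-EM and the FBS fusion.

The workhorse formulas:

* EM/OSEM multiplicative update with per-subset sensitivity
      x_EM,j = (x_j / s_j^(m)) * sum_{i in subset m} p_ij y_i / ybar_i
* the forward-backward-splitting fusion: the unique nonnegative maximiser of
      f(x) = x_EM ln x - x - (x - x_Reg)^2 / (2 gamma s)
  i.e. the positive root of  x^2 + (gamma s - x_Reg) x - gamma s x_EM = 0,
  evaluated in whichever of its two algebraically equivalent forms is
  numerically stable for the sign of b = 1 - x_Reg/(gamma s).

All fusion/EM arithmetic goes through the autodiff dispatch layer, so the
same code runs on plain arrays (classic reconstruction) and on tape tensors
(the learned unrolled network).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.special import gammaln

from . import autodiff as ad
from .sysmodel import EPS_DIV, SystemModel


@dataclass
class ReconTrajectory:
    """Per-module (subset update) sequence of image estimates."""

    images: list = field(default_factory=list)       # flat (N,) arrays
    n_iters: int = 0
    n_subsets: int = 1
    logliks: list = field(default_factory=list)

    @property
    def final(self) -> np.ndarray:
        return self.images[-1]

    def __len__(self):
        return len(self.images)

    def to_hdf5(self, path: str):
        with h5py.File(path, "w") as f:
            for k, img in enumerate(self.images):
                f.create_dataset(f"module_{k:03d}", data=img)
            f.attrs["n_iters"] = self.n_iters
            f.attrs["n_subsets"] = self.n_subsets
            if self.logliks:
                f.create_dataset("logliks", data=np.asarray(self.logliks))


@dataclass
class FusionInputs:
    """Inputs of the per-pixel fusion: EM image, regularised image, step, sensitivity."""

    x_em: np.ndarray
    x_reg: np.ndarray
    gamma: float
    sens: np.ndarray

    def solve(self):
        return fbs_fusion(self.x_em, self.x_reg, self.gamma, self.sens)


def poisson_loglik(y: np.ndarray, ybar: np.ndarray) -> float:
    """Poisson log-likelihood sum_i [y ln ybar - ybar - ln(y!)] (log-gamma form).

    Bins with ybar = 0 contribute 0 when y = 0 and -inf otherwise.
    """
    y = np.asarray(y, dtype=np.float64)
    ybar = np.asarray(ybar, dtype=np.float64)
    if np.any(y < 0) or np.any(ybar < 0):
        raise ValueError("y and ybar must be nonnegative")
    bad = (ybar == 0) & (y > 0)
    if np.any(bad):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(ybar > 0, ybar, 1.0)), 0.0)
    return float(np.sum(term - ybar - gammaln(y + 1)))


def em_update(x, y, sys: SystemModel, subset_id: int, r=0.0, s_sc=0.0,
              use_global_sens: bool = False):
    """One multiplicative EM update on one subset.

    `x` and the return value are flat (N,) arrays or autodiff tensors; `y` is
    the full-length measured sinogram (the subset rows are selected here).
    Division guards: denominators are floored at 1e-12, so pixels with zero
    sensitivity and bins with zero mean stay exactly zero.
    """
    rows = sys.subset_rows[subset_id]
    xd = x.data if isinstance(x, ad.Tensor) else np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if np.all(xd == 0) and np.any(y[rows] > 0):
        raise ValueError("all-zero estimate is a stalled EM fixed point")
    diag = sys.diag[rows]
    r_sub = (np.asarray(r)[rows] if np.ndim(r) else r)
    s_sub = (np.asarray(s_sc)[rows] if np.ndim(s_sc) else s_sc)
    ybar = ad.add(ad.mul(diag, ad.spmm(sys._sub_csr[subset_id], x,
                                       AT=sys._sub_csr_T[subset_id])),
                  np.asarray(r_sub + s_sub, dtype=np.float64))
    ratio = ad.div(y[rows], ad.maximum(ybar, EPS_DIV))
    back = ad.spmm(sys._sub_csr_T[subset_id], ad.mul(diag, ratio),
                   AT=sys._sub_csr[subset_id])
    sens = sys.sens if use_global_sens else sys.subset_sens[subset_id]
    return ad.div(ad.mul(x, back), np.maximum(sens, EPS_DIV))


def fbs_fusion(x_em, x_reg, gamma, sens):
    """Closed-form fusion of the EM and regularised images.

    Returns the nonnegative maximiser of
    x_em ln x - x - (x - x_reg)^2 / (2 gamma sens) per pixel; gamma may be
    np.inf, in which case the result is exactly x_em (pure EM).  Accepts
    plain arrays or autodiff tensors (gradients flow through x_em, x_reg
    and gamma).
    """
    g = gamma.data if isinstance(gamma, ad.Tensor) else gamma
    if np.any(np.asarray(g) <= 0):
        raise ValueError("gamma must be positive")
    if np.any(np.asarray(sens if not isinstance(sens, ad.Tensor) else sens.data) <= 0):
        raise ValueError("sensitivity must be positive in the fusion")
    gs = ad.mul(gamma, sens)
    with np.errstate(invalid="ignore", over="ignore"):
        b = ad.add(1.0, ad.mul(ad.div(x_reg, gs), -1.0))
        disc = ad.sqrt(ad.add(ad.mul(b, b), ad.mul(ad.div(x_em, gs), 4.0)))
        pos = ad.div(ad.mul(x_em, 2.0), ad.maximum(ad.add(b, disc), EPS_DIV))
        bd = b.data if isinstance(b, ad.Tensor) else b
        if np.all(np.asarray(bd) >= 0):
            return pos
        neg = ad.mul(ad.mul(gs, ad.add(disc, ad.mul(b, -1.0))), 0.5)
        return ad.where(np.asarray(bd) >= 0, pos, neg)


def mlem_reconstruct(y, sys: SystemModel, n_iters: int, init=None,
                     r=0.0, s_sc=0.0, check_monotone: bool = True) -> ReconTrajectory:
    """MLEM: full (single-subset) EM updates from a uniform-1 start.

    The Poisson log-likelihood is recorded every iteration and asserted
    non-decreasing (EM monotonicity) unless `check_monotone` is False.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.ones(sys.n_voxels) if init is None else np.asarray(init, dtype=np.float64).ravel().copy()
    if np.any(x < 0):
        raise ValueError("initial image must be nonnegative")
    rvec = np.broadcast_to(np.asarray(r, dtype=np.float64), y.shape)
    svec = np.broadcast_to(np.asarray(s_sc, dtype=np.float64), y.shape)
    traj = ReconTrajectory(n_iters=n_iters, n_subsets=1)
    prev_ll = -np.inf
    for _ in range(n_iters):
        ybar = sys.forward(x) + rvec + svec
        ratio = y / np.maximum(ybar, EPS_DIV)
        x = x * (sys.back(ratio)) / np.maximum(sys.sens, EPS_DIV)
        ll = poisson_loglik(y, sys.forward(x) + rvec + svec)
        if check_monotone and ll < prev_ll - 1e-6 * max(1.0, abs(prev_ll)):
            raise AssertionError("EM likelihood decreased — system model inconsistent")
        prev_ll = ll
        traj.images.append(x.copy())
        traj.logliks.append(ll)
    return traj


def osem_reconstruct(y, sys: SystemModel, n_iters: int,
                     n_subsets: int | None = None, init=None,
                     r=0.0, s_sc=0.0,
                     use_global_sens: bool = False) -> ReconTrajectory:
    """OSEM: cycles the angular subsets in fixed ascending order.

    The trajectory records every subset update (module-level granularity);
    with one subset this is exactly MLEM.
    """
    if n_subsets is None:
        n_subsets = sys.n_subsets
    if n_subsets != sys.n_subsets:
        raise ValueError("n_subsets must match the system model's subsetting")
    y = np.asarray(y, dtype=np.float64)
    x = np.ones(sys.n_voxels) if init is None else np.asarray(init, dtype=np.float64).ravel().copy()
    traj = ReconTrajectory(n_iters=n_iters, n_subsets=n_subsets)
    for _ in range(n_iters):
        for m in range(n_subsets):
            x = em_update(x, y, sys, m, r=r, s_sc=s_sc,
                          use_global_sens=use_global_sens)
            traj.images.append(x.copy())
    return traj


def _tikhonov_grad(x_img: np.ndarray, prior: str, shape) -> np.ndarray:
    if prior == "tikhonov":
        return 2.0 * x_img
    if prior == "smoothness":          # pairwise quadratic: 2 (x - local mean)
        img = x_img.reshape(shape)
        pad = np.pad(img, 1, mode="edge")
        if img.ndim == 2:
            local = (pad[:-2, 1:-1] + pad[2:, 1:-1] + pad[1:-1, :-2] + pad[1:-1, 2:]) / 4.0
        else:
            local = (pad[:-2, 1:-1, 1:-1] + pad[2:, 1:-1, 1:-1]
                     + pad[1:-1, :-2, 1:-1] + pad[1:-1, 2:, 1:-1]
                     + pad[1:-1, 1:-1, :-2] + pad[1:-1, 1:-1, 2:]) / 6.0
        return (2.0 * (img - local)).ravel()
    raise ValueError(f"unknown prior {prior!r}")


def mapem_tikhonov(y, sys: SystemModel, beta: float, gamma: float = 0.1,
                   n_iters: int = 10, n_subsets: int | None = None,
                   prior: str = "tikhonov", r=0.0, s_sc=0.0) -> ReconTrajectory:
    """MAP-EM with a quadratic prior via forward-backward splitting.

    Regularisation step: x_Reg = x - gamma*beta*grad R(x) with grad R = 2x
    (plain Tikhonov; `prior='smoothness'` swaps in a pairwise-quadratic
    gradient).  Fusion: the EM/regularisation fusion with proximal weight
    gamma_f = gamma / (2 beta), which is infinite at beta = 0 so the update
    then reduces exactly to OSEM.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    if n_subsets is None:
        n_subsets = sys.n_subsets
    if n_subsets != sys.n_subsets:
        raise ValueError("n_subsets must match the system model's subsetting")
    y = np.asarray(y, dtype=np.float64)
    x = np.ones(sys.n_voxels)
    gamma_f = np.inf if beta == 0 else gamma / (2.0 * beta)
    traj = ReconTrajectory(n_iters=n_iters, n_subsets=n_subsets)
    for _ in range(n_iters):
        for m in range(n_subsets):
            x_em = em_update(x, y, sys, m, r=r, s_sc=s_sc)
            x_reg = x - gamma * beta * _tikhonov_grad(x, prior, sys.grid.shape)
            sens = np.maximum(sys.subset_sens[m], EPS_DIV)
            x = fbs_fusion(x_em, x_reg, gamma_f, sens)
            traj.images.append(x.copy())
    return traj
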