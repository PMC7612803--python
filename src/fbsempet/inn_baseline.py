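"""Iterative neural-network (INN) baseline with a learned-threshold denoiser.

Alternates a trained denoising pass with a penalised-EM reconstruction
update.  The denoiser is a convolutional encoder-decoder (CED): one encoding
conv layer with K = 78 kernels, per-channel learned soft-thresholds
T(u, alpha) = sign(u) max(|u| - e^{-alpha}, 0) with alpha initialised at 15,
and one decoding conv layer back to a single channel; a residual-CNN variant
reuses the unrolled network's regulariser architecture.  The reconstruction
update is the exact positive root of the De Pierro-style penalised EM
surrogate,

    beta x^2 + (s - beta x_Reg) x - V = 0,
    V_j = x_j [P^T (y / (P x + r + s))]_j,

with an adaptive penalty strength

    beta = c ||s - P^T (y / (P x + r + s))||_2 / ||x - x_Reg||_2,

whose scale c (default 0.05) is the only user-set constant.  The denoisers
are iteration-dependent and trained sequentially against the final
noise-free-data reconstruction; no projector appears inside the denoiser
training step.  Initialisation: 10 MLEM iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .classic_recon import mlem_reconstruct
from .fbsem_net import RegularizerNet
from .phantoms import DatasetSample
from .sysmodel import EPS_DIV, SystemModel

BETA_CAP = 1e6


@dataclass(frozen=True)
class INNConfig:
    c: float = 0.05
    n_iters: int = 10
    n_init_em: int = 10
    n_kernels: int = 78
    alpha_init: float = 15.0
    regulariser: str = "CED"     # or "ResCNN"

    def __post_init__(self):
        if self.c <= 0:
            raise ValueError("step strength c must be positive")
        if self.regulariser not in ("CED", "ResCNN"):
            raise ValueError("regulariser must be 'CED' or 'ResCNN'")


def soft_threshold(u, alpha):
    """T(u, alpha) = sign(u) max(|u| - e^{-alpha}, 0), elementwise.

    Odd in u; differentiable a.e. in both u and alpha under autodiff.
    """
    sgn = np.sign(u.data if isinstance(u, Tensor) else np.asarray(u, dtype=np.float64))
    thr = ad.exp(ad.mul(alpha, -1.0))
    mag = ad.relu(ad.add(ad.absolute(u), ad.mul(thr, -1.0)))
    return ad.mul(sgn, mag)


class CEDNet(nn.Module):
    """Two-layer convolutional encoder-decoder with learned soft-thresholds."""

    def __init__(self, rng: np.random.Generator, n_kernels: int = 78,
                 alpha_init: float = 15.0, ndim: int = 2):
        k = (3,) * ndim
        self.encoder = nn.Conv(1, n_kernels, k, rng)
        self.alpha = nn.Parameter(np.full(n_kernels, alpha_init))
        self.decoder = nn.Conv(n_kernels, 1, k, rng, zero_init=True)
        self._ndim = ndim

    def __call__(self, x, training: bool = False):
        h = self.encoder(x)
        a = ad.reshape(self.alpha, (1, -1) + (1,) * self._ndim)
        return self.decoder(soft_threshold(h, a))


def ced_forward(x, net, grid_shape, training: bool = False):
    """Denoised image x_Reg from a flat image (array or tensor)."""
    img = ad.reshape(x, (1, 1) + tuple(grid_shape))
    if isinstance(net, RegularizerNet):
        # residual-CNN variant: the network output is the noise estimate
        out = ad.add(img, ad.mul(net(img, training=training), -1.0))
    else:
        out = net(img, training=training)
    return ad.reshape(out, (-1,))


def adaptive_beta(x, x_reg, y, sys: SystemModel, c: float,
                  r=0.0, s_sc=0.0) -> float:
    """beta = c ||s - P^T(y/ybar)||_2 / ||x - x_reg||_2 (capped at 1e6)."""
    x = np.asarray(x, dtype=np.float64).ravel()
    x_reg = np.asarray(x_reg, dtype=np.float64).ravel()
    ybar = sys.forward(x) + r + s_sc
    grad_like = sys.sens - sys.back(np.asarray(y) / np.maximum(ybar, EPS_DIV))
    num = c * float(np.linalg.norm(grad_like))
    den = float(np.linalg.norm(x - x_reg))
    if den == 0.0:
        if num == 0.0:
            return 0.0
        warnings.warn("x equals x_Reg: adaptive beta capped", RuntimeWarning)
        return BETA_CAP
    return min(num / den, BETA_CAP)


def inn_update(x, x_reg, beta: float, y, sys: SystemModel,
               r=0.0, s_sc=0.0) -> np.ndarray:
    """Penalised EM update: positive root of beta x^2 + (s - beta x_reg) x - V.

    Two algebraically equivalent branch formulas are used for numerical
    stability depending on the sign of lambda = (s - beta x_reg)/(2 beta);
    beta = 0 degenerates to the plain EM update V/s.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    x = np.asarray(x, dtype=np.float64).ravel()
    x_reg = np.asarray(x_reg, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64)
    ybar = sys.forward(x) + r + s_sc
    V = x * sys.back(y / np.maximum(ybar, EPS_DIV))
    s = sys.sens
    if beta == 0.0:
        return V / np.maximum(s, EPS_DIV)
    lam = (s - beta * x_reg) / (2.0 * beta)
    root = np.sqrt(lam ** 2 + V / beta)
    neg_branch = root - lam
    pos_branch = (V / beta) / np.maximum(root + lam, EPS_DIV)
    return np.where(lam < 0, neg_branch, pos_branch)


def inn_reconstruct(y, sys: SystemModel, nets: list, config: INNConfig,
                    r=0.0, s_sc=0.0):
    """Alternate denoising and penalised-EM updates from a 10-EM-iteration
    start; `nets` holds one trained denoiser per outer iteration."""
    x = mlem_reconstruct(y, sys, n_iters=config.n_init_em,
                         check_monotone=False).final
    traj = [x.copy()]
    for n in range(config.n_iters):
        with ad.no_grad():
            x_reg = ced_forward(Tensor(x), nets[n], sys.grid.shape).data
        beta = adaptive_beta(x, x_reg, y, sys, config.c, r=r, s_sc=s_sc)
        x = inn_update(x, x_reg, beta, y, sys, r=r, s_sc=s_sc)
        traj.append(x.copy())
    return x, traj


def inn_train(train_samples: list[DatasetSample], config: INNConfig,
              lr: float = 0.01, epochs: int = 10, seed: int = 0):
    """Sequentially train one denoiser per outer iteration.

    Each denoiser is optimised (Adam, MSE) to map the current reconstruction
    of every training sample to that sample's final noise-free-data target;
    the reconstruction update then advances all samples one outer iteration.
    Returns (nets, per-iteration mean denoiser losses).
    """
    rng = np.random.default_rng(seed)
    sys = train_samples[0].sys
    ndim = 2 if sys.grid.nz is None else 3
    xs = [mlem_reconstruct(s.low.y, s.sys, n_iters=config.n_init_em,
                           check_monotone=False).final
          for s in train_samples]
    finals = [s.targets.final for s in train_samples]
    nets, losses = [], []
    for n in range(config.n_iters):
        if config.regulariser == "CED":
            net = CEDNet(rng, config.n_kernels, config.alpha_init, ndim)
        else:
            net = RegularizerNet(rng, ndim=ndim)
        opt = nn.Adam(net.parameters(), lr=lr)
        ep_losses = []
        for _ in range(epochs):
            tot = 0.0
            for i in rng.permutation(len(train_samples)):
                ad.ledger.start_step()
                out = ced_forward(Tensor(xs[i]), net,
                                  train_samples[i].sys.grid.shape, training=True)
                diff = ad.add(out, ad.mul(finals[i], -1.0))
                loss = ad.mul(ad.sum_(ad.mul(diff, diff)), 1.0 / finals[i].size)
                opt.zero_grad()
                loss.backward()
                opt.step()
                tot += loss.item()
            ep_losses.append(tot / len(train_samples))
        losses.append(ep_losses)
        nets.append(net)
        for i, s in enumerate(train_samples):
            with ad.no_grad():
                x_reg = ced_forward(Tensor(xs[i]), net, s.sys.grid.shape).data
            beta = adaptive_beta(xs[i], x_reg, s.low.y, s.sys, config.c)
            xs[i] = inn_update(xs[i], x_reg, beta, s.low.y, s.sys)
    return nets, losses
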