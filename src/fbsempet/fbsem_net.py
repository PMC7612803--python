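"""Unrolled forward-backward-splitting EM network.

Each unrolled module performs, for one angular subset,

    1. the multiplicative EM update (data consistency),
    2. a learned regularisation step  x_Reg = x - gamma * F(x; theta)
       with F a small residual CNN (5 conv layers, 32 kernels of 3x3,
       batch norm + ReLU after layers 1-4, linear 1-channel output),
    3. the closed-form fusion of the two images.

A chain of n_iters x n_subsets modules (default 10 x 6 = 60) either shares
one regulariser across modules or gives every module its own
iteration-dependent network.  gamma is a trainable positive scalar
(softplus-parameterised, initialised at 0.5), one per module when networks
are iteration-dependent, shared otherwise.  The fusion guarantees
nonnegative outputs regardless of the network output, and the whole chain
is differentiable with respect to theta and gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .classic_recon import ReconTrajectory, em_update, fbs_fusion
from .sysmodel import EPS_DIV, SystemModel


def _inverse_softplus(y: float) -> float:
    if y > 30:          # softplus(y) == y to double precision
        return float(y)
    return float(np.log(np.expm1(y)))


@dataclass(frozen=True)
class FBSEMConfig:
    """Chain structure and parameterisation flags."""

    n_iters: int = 10
    n_subsets: int = 6
    iteration_dependent_nets: bool = True
    gamma_init: float = 0.5
    n_channels: int = 32
    internal_skip: bool = False
    global_sens_mode: bool = False   # global instead of per-subset sensitivity

    @property
    def n_modules(self) -> int:
        return self.n_iters * self.n_subsets


class RegularizerNet(nn.Module):
    """Residual CNN producing the gradient-like correction F(x; theta).

    Five convolutional layers with `n_channels` kernels of size 3^d; the
    final layer maps to one channel with no activation and is
    zero-initialised so an untrained chain starts in the OSEM-like regime.
    With `internal_skip` the network output is x + stack(x) instead of
    stack(x) (the residual connection is otherwise the subtraction in the
    regularisation step itself).
    """

    def __init__(self, rng: np.random.Generator, n_channels: int = 32,
                 ndim: int = 2, internal_skip: bool = False):
        k = (3,) * ndim
        self.conv1 = nn.Conv(1, n_channels, k, rng)
        self.bn1 = nn.BatchNorm(n_channels)
        self.conv2 = nn.Conv(n_channels, n_channels, k, rng)
        self.bn2 = nn.BatchNorm(n_channels)
        self.conv3 = nn.Conv(n_channels, n_channels, k, rng)
        self.bn3 = nn.BatchNorm(n_channels)
        self.conv4 = nn.Conv(n_channels, n_channels, k, rng)
        self.bn4 = nn.BatchNorm(n_channels)
        self.conv5 = nn.Conv(n_channels, 1, k, rng, zero_init=True)
        self._skip = internal_skip

    def __call__(self, x, training: bool = False):
        h = ad.relu(self.bn1(self.conv1(x), training))
        h = ad.relu(self.bn2(self.conv2(h), training))
        h = ad.relu(self.bn3(self.conv3(h), training))
        h = ad.relu(self.bn4(self.conv4(h), training))
        out = self.conv5(h)
        if self._skip:
            out = ad.add(x, out)
        return out


class ModuleChain:
    """Ordered unrolled modules with their regulariser and gamma handles."""

    def __init__(self, config: FBSEMConfig, seed: int = 0, ndim: int = 2):
        self.config = config
        rng = np.random.default_rng(seed)
        raw0 = _inverse_softplus(config.gamma_init)
        n = config.n_modules
        if config.iteration_dependent_nets:
            self.nets = [RegularizerNet(rng, config.n_channels, ndim,
                                        config.internal_skip) for _ in range(n)]
            self.gamma_raw = [nn.Parameter(raw0) for _ in range(n)]
        else:
            net = RegularizerNet(rng, config.n_channels, ndim, config.internal_skip)
            self.nets = [net] * n
            g = nn.Parameter(raw0)
            self.gamma_raw = [g] * n
        self.ndim = ndim

    @property
    def n_modules(self) -> int:
        return self.config.n_modules

    def subset_of(self, k: int) -> int:
        return k % self.config.n_subsets

    def gamma(self, k: int):
        """Positive fusion step of module k (softplus of the raw parameter)."""
        return ad.softplus(self.gamma_raw[k])

    def module_parameters(self, k: int) -> list[Tensor]:
        return self.nets[k].parameters() + [self.gamma_raw[k]]

    def parameters(self) -> list[Tensor]:
        seen, out = set(), []
        for k in range(self.n_modules):
            for p in self.module_parameters(k):
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- checkpointing -------------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        if self.config.iteration_dependent_nets:
            for k in range(self.n_modules):
                state.update(self.nets[k].state_dict(prefix=f"module{k:03d}."))
                state[f"gamma_raw{k:03d}"] = self.gamma_raw[k].data.copy()
        else:
            state.update(self.nets[0].state_dict(prefix="shared."))
            state["gamma_raw"] = self.gamma_raw[0].data.copy()
        return state

    def load_state_dict(self, state: dict):
        if self.config.iteration_dependent_nets:
            for k in range(self.n_modules):
                self.nets[k].load_state_dict(state, prefix=f"module{k:03d}.")
                self.gamma_raw[k].data = np.array(state[f"gamma_raw{k:03d}"])
        else:
            self.nets[0].load_state_dict(state, prefix="shared.")
            self.gamma_raw[0].data = np.array(state["gamma_raw"])

    def save(self, path: str):
        np.savez(path, **self.state_dict())

    def load(self, path: str):
        with np.load(path) as f:
            self.load_state_dict({k: f[k] for k in f.files})


def reg_step(x, net: RegularizerNet, gamma, grid_shape, training: bool = False):
    """x_Reg = x - gamma * F(x); may be negative, the fusion handles that.

    `x` is a flat (N,) array or tensor; the network sees it as (1, 1, *shape).
    """
    img = ad.reshape(x, (1, 1) + tuple(grid_shape))
    corr = net(img, training=training)
    flat = ad.reshape(corr, (-1,))
    return ad.add(x, ad.mul(ad.mul(gamma, flat), -1.0))


def fbsem_module(x_prev, y, sys: SystemModel, subset_id: int,
                 net: RegularizerNet, gamma, training: bool = False,
                 global_sens_mode: bool = False):
    """One unrolled module: EM update, learned regularisation, fusion."""
    x_em = em_update(x_prev, y, sys, subset_id,
                     use_global_sens=global_sens_mode)
    x_reg = reg_step(x_prev, net, gamma, sys.grid.shape, training=training)
    sens = sys.sens if global_sens_mode else sys.subset_sens[subset_id]
    return fbs_fusion(x_em, x_reg, gamma, np.maximum(sens, EPS_DIV))


def fbsem_forward(y, sys: SystemModel, chain: ModuleChain,
                  n_modules: int | None = None, training: bool = False,
                  x0=None) -> ReconTrajectory:
    """Run the unrolled chain from the uniform initial image.

    Supports early stopping at any module count <= the chain length; the
    trajectory records every module output (as plain arrays).
    """
    cfg = chain.config
    if cfg.n_subsets != sys.n_subsets:
        raise ValueError("chain subsets do not match the system model")
    n = chain.n_modules if n_modules is None else int(n_modules)
    if not 1 <= n <= chain.n_modules:
        raise ValueError("n_modules out of range")
    x = Tensor(np.ones(sys.n_voxels)) if x0 is None else ad.as_tensor(x0)
    traj = ReconTrajectory(n_iters=cfg.n_iters, n_subsets=cfg.n_subsets)
    for k in range(n):
        x = fbsem_module(x, y, sys, chain.subset_of(k), chain.nets[k],
                         chain.gamma(k), training=training,
                         global_sens_mode=cfg.global_sens_mode)
        traj.images.append(np.array(x.data if isinstance(x, Tensor) else x))
    return traj
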