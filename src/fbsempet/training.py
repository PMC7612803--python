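"""Target construction and training regimes for the unrolled network.

Supervision is iteration-dependent: module k of the unrolled chain is
trained to match iterate k of a deterministic OSEM reconstruction of the
noise-free (high-count) data, brought to the intensity scale of the
low-count measurements.  Four regimes are provided:

* ``end_to_end_final`` — one MSE loss on the last module's output against
  the final target, backpropagated through the whole chain (the original
  shared-regulariser formulation trains this way);
* ``end_to_end_IS``    — the sum of one MSE term per module, each against
  its own iteration-dependent target;
* ``sequential_IS``    — one module at a time: the frozen prefix produces
  the module's input with no gradient retention, the module is optimised
  against its own target, then frozen.  Peak retained-activation memory is
  that of a single module, independent of chain depth (tracked by the
  activation ledger);
* ``leapfrog``         — a short chain of k modules trained to match the
  final (deepest) target; the leapfrog factor is n_targets / k.

Optimiser: Adam (lr 0.01, 50 epochs, mini-batch 5 for 2D; lr 0.005,
100 epochs, batch 1 for 3D), MSE loss throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .classic_recon import fbs_fusion, osem_reconstruct
from .fbsem_net import ModuleChain
from .phantoms import DatasetSample
from .sysmodel import EPS_DIV, SystemModel

REGIMES = ("end_to_end_final", "end_to_end_IS", "sequential_IS", "leapfrog")


@dataclass
class TrainingConfig:
    lr: float = 0.01
    epochs: int = 50
    batch_size: int = 5
    regime: str = "sequential_IS"
    seed: int = 0
    epochs_per_module: int | None = None   # sequential: defaults to `epochs`

    def __post_init__(self):
        if self.lr < 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("lr must be >= 0, epochs and batch_size >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}")

    @property
    def module_epochs(self) -> int:
        return self.epochs if self.epochs_per_module is None else self.epochs_per_module


@dataclass
class TargetSet:
    """Per-module OSEM iterates of the noise-free data (module-aligned)."""

    images: list = field(default_factory=list)

    @property
    def final(self) -> np.ndarray:
        return self.images[-1]

    def __len__(self):
        return len(self.images)


def build_iteration_targets(sample: DatasetSample, n_iters: int = 10,
                            n_subsets: int = 6) -> TargetSet:
    """Deterministic OSEM trajectory of the noise-free data, one image per
    subset update, on the low-count intensity scale.

    The high-count mean sinogram is rescaled by scale_low/scale_high before
    reconstruction so the targets share the intensity scale of the low-count
    reconstructions they supervise.
    """
    y_nf = sample.high.ybar * (sample.scale_low / sample.scale_high)
    traj = osem_reconstruct(y_nf, sample.sys, n_iters=n_iters, n_subsets=n_subsets)
    ts = TargetSet(images=list(traj.images))
    sample.targets = ts
    return ts


# ---------------------------------------------------------------------------
# batched chain execution


class _Batch:
    """Stacked per-sample constants for vectorised training: images are
    (N, B) matrices, sinograms (M, B)."""

    def __init__(self, samples: list[DatasetSample]):
        sys0 = samples[0].sys
        self.sys = sys0
        self.n = len(samples)
        self.Y = np.stack([s.low.y for s in samples], axis=1)
        self.diag = np.stack([s.sys.diag for s in samples], axis=1)
        self.subset_sens = np.stack(
            [np.stack([s.sys.subset_sens[m] for s in samples], axis=1)
             for m in range(sys0.n_subsets)])
        if samples[0].targets is not None:
            self.targets = np.stack(
                [np.stack([s.targets.images[k] for s in samples], axis=1)
                 for k in range(len(samples[0].targets))])
        else:
            self.targets = None

    def cols(self, idx):
        sub = object.__new__(_Batch)
        sub.sys = self.sys
        sub.n = len(idx)
        sub.Y = self.Y[:, idx]
        sub.diag = self.diag[:, idx]
        sub.subset_sens = self.subset_sens[:, :, idx]
        sub.targets = self.targets[:, :, idx] if self.targets is not None else None
        return sub


def _module_forward_batch(chain: ModuleChain, k: int, x, batch: _Batch,
                          training: bool):
    """One unrolled module applied to an (N, B) batch of image columns."""
    sys = batch.sys
    m = chain.subset_of(k)
    strict = chain.config.global_sens_mode
    rows = sys.subset_rows[m]
    A, AT = sys._sub_csr[m], sys._sub_csr_T[m]
    diag = batch.diag[rows]
    ybar = ad.mul(diag, ad.spmm(A, x, AT=AT))
    ratio = ad.div(batch.Y[rows], ad.maximum(ybar, EPS_DIV))
    back = ad.spmm(AT, ad.mul(diag, ratio), AT=A)
    if strict:
        sens = np.maximum(batch.subset_sens.sum(axis=0), EPS_DIV)
    else:
        sens = np.maximum(batch.subset_sens[m], EPS_DIV)
    x_em = ad.div(ad.mul(x, back), sens)
    # learned regularisation on the image-shaped batch
    H = sys.grid.shape
    img = ad.reshape(ad.transpose(x, (1, 0)), (batch.n, 1) + tuple(H))
    corr = chain.nets[k](img, training=training)
    flat = ad.transpose(ad.reshape(corr, (batch.n, -1)), (1, 0))
    gamma = chain.gamma(k)
    x_reg = ad.add(x, ad.mul(ad.mul(gamma, flat), -1.0))
    return fbs_fusion(x_em, x_reg, gamma, sens)


def _chain_forward_batch(chain: ModuleChain, batch: _Batch, n_modules: int,
                         training: bool, record: bool = False, x0=None):
    x = Tensor(np.ones((batch.sys.n_voxels, batch.n))) if x0 is None else x0
    outs = []
    for k in range(n_modules):
        x = _module_forward_batch(chain, k, x, batch, training)
        if record:
            outs.append(x)
    return (x, outs) if record else (x, None)


def _mse(a, b) -> object:
    diff = ad.add(a, ad.mul(b, -1.0))
    return ad.mul(ad.sum_(ad.mul(diff, diff)), 1.0 / np.asarray(
        b.data if isinstance(b, Tensor) else b).size)


def _epoch_batches(rng: np.random.Generator, n: int, batch_size: int):
    perm = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield perm[i:i + batch_size]


def _calibrate_chain(chain: ModuleChain, batch: _Batch, n_modules: int):
    """Set every regulariser's batch-norm running averages to the exact
    statistics of one training-mode pass over `batch` (the full training
    set), so inference-mode forwards match what training saw."""
    seen, restores = set(), []
    for k in range(n_modules):
        if id(chain.nets[k]) not in seen:
            seen.add(id(chain.nets[k]))
            restores.append(nn.calibrate_batchnorm(chain.nets[k]))
    with ad.no_grad():
        _chain_forward_batch(chain, batch, n_modules, training=True)
    for r in restores:
        r()


def _val_loss(chain: ModuleChain, val_batch: _Batch | None, n_modules: int) -> float:
    if val_batch is None:
        return np.nan
    with ad.no_grad():
        out, _ = _chain_forward_batch(chain, val_batch, n_modules, training=False)
    return float(np.mean((out.data - val_batch.targets[n_modules - 1]) ** 2))


def train_end_to_end(train_samples: list[DatasetSample], chain: ModuleChain,
                     config: TrainingConfig,
                     val_samples: list[DatasetSample] | None = None,
                     final_target_index: int | None = None):
    """Full backpropagation through the chain (final-loss or IS variants).

    Returns (chain, loss_log).  The best-validation parameters (final-module
    MSE on the validation set) are restored at the end.
    """
    if config.regime not in ("end_to_end_final", "end_to_end_IS", "leapfrog"):
        raise ValueError("train_end_to_end expects an end-to-end regime")
    batch = _Batch(train_samples)
    val_batch = _Batch(val_samples) if val_samples else None
    n_mod = chain.n_modules
    tgt_idx = n_mod - 1 if final_target_index is None else final_target_index
    opt = nn.Adam(chain.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed)
    log, best = [], (np.inf, None)
    for epoch in range(config.epochs):
        ep_loss, n_batches = 0.0, 0
        for idx in _epoch_batches(rng, batch.n, config.batch_size):
            sub = batch.cols(idx)
            ad.ledger.start_step()
            record = config.regime == "end_to_end_IS"
            out, outs = _chain_forward_batch(chain, sub, n_mod, training=True,
                                             record=record)
            if config.regime == "end_to_end_IS":
                loss = _mse(outs[0], sub.targets[0])
                for k in range(1, n_mod):
                    loss = ad.add(loss, _mse(outs[k], sub.targets[k]))
            else:
                loss = _mse(out, sub.targets[tgt_idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            ep_loss += loss.item()
            n_batches += 1
        _calibrate_chain(chain, batch, n_mod)
        vl = _val_loss(chain, val_batch, n_mod)
        log.append({"epoch": epoch, "module": n_mod,
                    "train_loss": ep_loss / n_batches, "val_loss": vl})
        score = vl if val_batch is not None else ep_loss / n_batches
        if score <= best[0]:
            best = (score, chain.state_dict())
    if best[1] is not None:
        chain.load_state_dict(best[1])
    return chain, log


def train_sequential(train_samples: list[DatasetSample], chain: ModuleChain,
                     config: TrainingConfig,
                     val_samples: list[DatasetSample] | None = None):
    """Train one module at a time against its own iteration-dependent target.

    The already-trained prefix is run once per module in inference mode (no
    tape), so retained activations never exceed one module's worth; frozen
    parameters are untouched bit-for-bit.
    """
    if not chain.config.iteration_dependent_nets and chain.n_modules > 1:
        raise ValueError("sequential training needs iteration-dependent networks")
    batch = _Batch(train_samples)
    rng = np.random.default_rng(config.seed)
    X_cur = np.ones((batch.sys.n_voxels, batch.n))
    log = []
    for k in range(chain.n_modules):
        opt = nn.Adam(chain.module_parameters(k), lr=config.lr)
        for epoch in range(config.module_epochs):
            ep_loss, n_batches = 0.0, 0
            for idx in _epoch_batches(rng, batch.n, config.batch_size):
                sub = batch.cols(idx)
                ad.ledger.start_step()
                out = _module_forward_batch(chain, k, Tensor(X_cur[:, idx]),
                                            sub, training=True)
                loss = _mse(out, sub.targets[k])
                if not np.isfinite(loss.item()):
                    raise FloatingPointError(
                        f"module {k} diverged at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                ep_loss += loss.item()
                n_batches += 1
            log.append({"epoch": epoch, "module": k,
                        "train_loss": ep_loss / n_batches, "val_loss": np.nan})
        # freeze: pin batch-norm running averages to the full-set statistics,
        # then advance the frozen prefix (inference mode, no tape)
        restore = nn.calibrate_batchnorm(chain.nets[k])
        with ad.no_grad():
            _module_forward_batch(chain, k, Tensor(X_cur), batch, training=True)
        restore()
        with ad.no_grad():
            X_cur = _module_forward_batch(chain, k, Tensor(X_cur), batch,
                                          training=False).data
    return chain, log


def train_leapfrog(train_samples: list[DatasetSample], chain: ModuleChain,
                   config: TrainingConfig, n_targets: int = 60,
                   val_samples: list[DatasetSample] | None = None):
    """Short chain of k modules trained to match the deepest (n_targets-th)
    target; returns (chain, log, leapfrog_factor = n_targets / k)."""
    k = chain.n_modules
    if k > n_targets:
        raise ValueError("chain cannot be deeper than the target trajectory")
    cfg = TrainingConfig(lr=config.lr, epochs=config.epochs,
                         batch_size=config.batch_size, regime="leapfrog",
                         seed=config.seed)
    chain, log = train_end_to_end(train_samples, chain, cfg,
                                  val_samples=val_samples,
                                  final_target_index=n_targets - 1)
    return chain, log, n_targets / k


def train(train_samples, chain, config: TrainingConfig, val_samples=None):
    """Dispatch on config.regime."""
    if config.regime == "sequential_IS":
        return train_sequential(train_samples, chain, config, val_samples)
    if config.regime == "leapfrog":
        chain, log, _ = train_leapfrog(train_samples, chain, config,
                                       n_targets=len(train_samples[0].targets),
                                       val_samples=val_samples)
        return chain, log
    return train_end_to_end(train_samples, chain, config, val_samples)


def save_loss_log(path: str, log: list[dict]):
    with open(path, "w") as f:
        f.write("epoch,module,train_loss,val_loss\n")
        for row in log:
            f.write(f"{row['epoch']},{row['module']},"
                    f"{row['train_loss']:.10g},{row['val_loss']:.10g}\n")
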