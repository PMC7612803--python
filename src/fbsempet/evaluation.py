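"""Reconstruction quality metrics and the multi-realisation bias/SD study.

NRMSE is the root-mean-square error normalised by the mean of the target
dataset.  The bias/SD study reconstructs S independent Poisson realisations
of one phantom's low-count data and decomposes the ensemble RMSE against
the ground-truth phantom (not the high-count reconstruction) into

    bias = sqrt( sum_j (xbar_j - ref_j)^2 / sum_j ref_j^2 )
    SD   = sqrt( (1/S) sum_s sum_j (x_j^(s) - xbar_j)^2 / sum_j ref_j^2 )

so that RMSE^2 = bias^2 + SD^2 holds exactly.  No subsets are used in this
study (plain MLEM-style full updates), and the voxel set defaults to the
brain mask (activity support).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classic_recon import ReconTrajectory, mlem_reconstruct
from .sysmodel import SystemModel, sample_poisson, scale_to_counts


def nrmse(x: np.ndarray, ref: np.ndarray, dataset_mean: float) -> float:
    """sqrt(mean((x - ref)^2)) / dataset_mean."""
    if dataset_mean <= 0:
        raise ValueError("dataset_mean must be positive")
    x = np.asarray(x, dtype=np.float64).ravel()
    ref = np.asarray(ref, dtype=np.float64).ravel()
    return float(np.sqrt(np.mean((x - ref) ** 2)) / dataset_mean)


def per_module_curves(trajectory, targets) -> tuple[np.ndarray, np.ndarray]:
    """Per-module MSE curves of an unrolled reconstruction.

    Curve A: MSE of every module's output against the final target.
    Curve B: MSE of every module's output against its own
    iteration-dependent target.  Both have one entry per module.
    """
    imgs = trajectory.images if isinstance(trajectory, ReconTrajectory) else list(trajectory)
    tgts = targets.images if hasattr(targets, "images") else list(targets)
    if len(imgs) != len(tgts):
        raise ValueError("trajectory and target lengths differ")
    final = np.asarray(tgts[-1]).ravel()
    a = np.array([np.mean((np.asarray(x).ravel() - final) ** 2) for x in imgs])
    b = np.array([np.mean((np.asarray(x).ravel() - np.asarray(t).ravel()) ** 2)
                  for x, t in zip(imgs, tgts)])
    return a, b


def aggregate_curves(curves: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SD over runs (the shaded-area analogue of loss-curve plots)."""
    arr = np.stack(curves)
    return arr.mean(axis=0), arr.std(axis=0)


@dataclass
class BiasSDResult:
    """Bias/SD/RMSE records per method and module count (S realisations)."""

    method: str
    S: int
    records: list = field(default_factory=list)   # dicts with module_count/bias/sd/rmse

    def to_csv(self, path: str):
        with open(path, "w") as f:
            f.write("method,module_count,bias,sd,rmse\n")
            for r in self.records:
                f.write(f"{self.method},{r['module_count']},"
                        f"{r['bias']:.10g},{r['sd']:.10g},{r['rmse']:.10g}\n")


def bias_sd_study(method, sys: SystemModel, phantom: np.ndarray, S: int,
                  module_counts: list[int], seed: int,
                  counts: float = 5e5, omega: np.ndarray | None = None,
                  method_name: str = "mlem") -> BiasSDResult:
    """Ensemble bias/SD/RMSE over S Poisson realisations of one phantom.

    `method` is either the string "mlem" or a callable
    (y, sys, n_iters) -> ReconTrajectory run with subsets forced to 1.
    The reference is the ground-truth phantom on the count scale of the
    simulated data; `omega` defaults to the activity support.
    """
    if S < 2:
        raise ValueError("need S >= 2 realisations for an ensemble SD")
    phantom = np.asarray(phantom, dtype=np.float64)
    ybar, factor = scale_to_counts(sys.forward(phantom), counts)
    ref = (phantom * factor).ravel()
    mask = (phantom > 0).ravel() if omega is None else np.asarray(omega, dtype=bool).ravel()
    ref_m = ref[mask]
    denom = float(np.sum(ref_m ** 2))
    n_max = max(module_counts)
    rng = np.random.default_rng(seed)
    recons = {n: [] for n in module_counts}
    for _ in range(S):
        y = sample_poisson(ybar, int(rng.integers(0, 2 ** 31 - 1)))
        if method == "mlem":
            traj = mlem_reconstruct(y, sys, n_iters=n_max, check_monotone=False)
        else:
            traj = method(y, sys, n_max)
        for n in module_counts:
            recons[n].append(traj.images[n - 1].ravel()[mask])
    result = BiasSDResult(method=method_name, S=S)
    for n in module_counts:
        X = np.stack(recons[n])                      # (S, |omega|)
        xbar = X.mean(axis=0)
        bias2 = float(np.sum((xbar - ref_m) ** 2)) / denom
        sd2 = float(np.mean(np.sum((X - xbar) ** 2, axis=1))) / denom
        rmse2 = float(np.mean(np.sum((X - ref_m) ** 2, axis=1))) / denom
        result.records.append({"module_count": n,
                               "bias": float(np.sqrt(bias2)),
                               "sd": float(np.sqrt(sd2)),
                               "rmse": float(np.sqrt(rmse2))})
    return result


def plot_bias_sd(result: BiasSDResult, path: str):
    """Bias-vs-SD trade-off curve (one marker per module count) to PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sd = [r["sd"] for r in result.records]
    bias = [r["bias"] for r in result.records]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(sd, bias, "o-")
    for r in result.records:
        ax.annotate(str(r["module_count"]), (r["sd"], r["bias"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("standard deviation")
    ax.set_ylabel("bias")
    ax.set_title(f"{result.method}, S={result.S}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
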