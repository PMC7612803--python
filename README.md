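# fbsempet

Unrolled MAP-EM reconstruction for emission tomography with learned,
iteration-dependent regularisation — simulated end to end at desk scale.

## The problem

PET measurements are Poisson counts `y` with mean `ȳ = Px + r + s`, where
`P` is the system matrix (geometric projector × image-space PSF ×
attenuation/normalisation factors) and `x` the activity image.  Maximum-
likelihood reconstruction (MLEM/OSEM) fits the noise at clinically useful
count levels, so regularisation is needed.  This package implements a
forward-backward-splitting EM network (FBSEM): the MAP-EM algorithm is
unrolled into modules, one per OSEM subset update, and the regularisation
step of each module is a small residual CNN whose parameters — and the
fusion step size γ — are learned from data.  One module computes

1. the EM update
   `x_EM,j = (x_j / s_j) · Σ_i p_ij · y_i / (Σ_k p_ik x_k + r_i + s_i)`,
2. the learned regularisation step `x_Reg = x − γ·F(x; θ)`,
3. the closed-form fusion: the nonnegative maximiser of
   `x_EM ln x − x − (x − x_Reg)² / (2 γ s_j)`, i.e. the positive root of
   `x² + (γ s_j − x_Reg) x − γ s_j x_EM = 0`.

The iteration-specific variant gives every module its own network `θⁿ` and
supervises every module's output against the matching OSEM iterate of
noise-free data (iteration-dependent targets), which constrains the
networks to remain pure denoisers.  Sequential training — one module at a
time, with the frozen prefix run without gradient retention — makes the
activation memory of training independent of the chain depth.

Everything runs on synthetic data: procedural brain-like phantoms
(GM/WM/CSF/skull/skin, uptake 96/32/0/0/16 with hot lesions of 2–8 mm
radius), attenuation maps (0.13/0.0975/0 cm⁻¹), a 2D parallel-beam sparse
projector with exact adjoint, 2.5 mm FWHM PSF, per-bin normalisation and
Poisson noise at configurable count levels.  The networks and their
training (Adam, MSE) run on a small reverse-mode autodiff engine included
in the package, so there is no deep-learning framework dependency.

Also included: MLEM/OSEM/MAP-EM(Tikhonov) baselines, an iterative-NN
baseline (convolutional encoder-decoder with learned soft-thresholds,
adaptive penalty strength and a closed-form penalised EM update), and a
bias/SD/RMSE study over independent noise realisations.

## Worked example

```bash
python examples/02_train_unrolled_network.py
```

trains a 12-module chain (2 iterations × 6 subsets, 32×32 grid, 16
training phantoms) sequentially and prints:

```
chain: 12 modules, 343320 parameters
module 1 loss 3.66e-04 -> module 12 loss 4.93e-03 (different targets per module)
held-out NRMSE, learned chain: 0.5900   OSEM: 0.6017
```

Each module's MSE is measured against its own iteration-dependent target
(the matching OSEM iterate of noise-free data); the held-out NRMSE —
RMSE divided by the mean of the target dataset — shows the learned chain
beating unregularised OSEM at the same module count.  The other examples
cover classical reconstruction (`01`), the constant-memory contract of
sequential training (`03`, a ~98% cut versus end-to-end training of a
60-module chain), the iterative-NN baseline (`04`), and the bias/SD
trade-off across MLEM iteration counts (`05`).

A thin CLI wraps the same library:

```bash
fbsempet simulate -o geometry.nx=32 -o dataset.n_train=4   # dataset HDF5
fbsempet reconstruct --method osem                         # image + trajectory
fbsempet train / evaluate / biassd                         # see --help
```

## Layout

- `src/fbsempet/sysmodel.py` — grids, projector, PSF, attenuation, subsets, Poisson sampling
- `src/fbsempet/phantoms.py` — procedural phantoms, lesions, datasets
- `src/fbsempet/classic_recon.py` — likelihood, MLEM/OSEM, fusion, MAP-EM
- `src/fbsempet/fbsem_net.py` — regulariser CNN, unrolled module chain
- `src/fbsempet/training.py` — targets, end-to-end / sequential / leapfrog training
- `src/fbsempet/inn_baseline.py` — CED denoiser, adaptive β, penalised EM update
- `src/fbsempet/evaluation.py` — NRMSE, per-module curves, bias/SD study
- `src/fbsempet/autodiff.py`, `nn.py` — reverse-mode autodiff, conv/batch-norm/Adam
- `src/fbsempet/config.py`, `cli.py` — YAML experiment configs and the CLI

See `docs/methods.md` for the model details, parameter choices and known
limitations.
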