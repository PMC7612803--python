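# Methods

## Forward model

Measured sinogram counts are modelled as independent Poisson draws with
mean `ȳ = Px + r + s`.  The system matrix factorises as
`P = diag(a·n) · G · H`:

- `G` — 2D parallel-beam geometric projector.  Rays are sampled at half a
  pixel pitch with bilinear interpolation of the image at each sample
  point; weights carry the mm step so that a row of `G` applied to an
  image is a line integral in value·mm.  `G` is an explicit sparse
  matrix, so the adjoint used by EM is exact (verified to 1e−10 relative
  in the tests).  Defaults: 96×96 grid at 2.08 mm pixels, 120 angles
  uniformly spaced in [0, π), 128 radial bins at pixel pitch; the test
  configuration is 32×32 / 48 angles / 48 bins.
- `H` — image-space Gaussian PSF, σ = FWHM / (2√(2 ln 2)), default FWHM
  2.5 mm, built as a Kronecker product of 1D blur matrices whose columns
  are renormalised at the image edge (mass preserving; interior rows sum
  to one, so uniform images are interior fixed points).
- `a` — attenuation survival factors `exp(−∫μ dl)` with μ in cm⁻¹ on the
  image grid (values 0.13 skull / 0.0975 soft tissue / 0 air).
- `n` — per-bin detector efficiencies, uniform in [0.8, 1.2] under a
  dedicated seed (on by default; the generating values are not otherwise
  meaningful, only that normalisation is modelled).

Randoms `r` and scatters `s` are carried through every API as optional
terms but default to zero; their physics is not simulated.

Subsets partition the sinogram rows round-robin over projection angles
(angle k → subset k mod N_subsets) and are always cycled in fixed
ascending order, so runs are deterministic.  Per-subset sensitivity images
`s_j^(m) = Σ_{i∈subset m} p_ij` are precomputed; their sum equals the
global sensitivity elementwise.

Division guards: every EM-style ratio floors its denominator at 1e−12;
pixels with zero sensitivity and bins with zero mean therefore stay
exactly zero rather than producing NaNs.

## Phantoms and datasets

Brain-like piecewise-constant anatomy is built from nested ellipses with
random eccentricity, centre jitter and rotation: a skin ring, a skull
ring, a CSF rim, a grey-matter ribbon obtained by binary erosion of the
brain mask (ribbon width ≈ 6 mm), and a white-matter core.  Region uptake:
GM ~ N(96, 5²), WM ~ N(32, 5²) (truncated at zero, one value per region
per sample — activity is exactly piecewise constant over the label map),
skin 16, CSF and skull 0.  Alternative test distributions shift
(WM, GM, skin) to (64, 80, 32) and (5, 120, 32).  Circular hot lesions
(uniform radius 2–8 mm, centres uniform over the brain interior, clipped
by the brain mask) are set to 1.3× the sample's GM value; the contrast
factor and the per-sample lesion count (uniform {1, 2, 3}) are package
choices, since only the radius range and "hot" are prescribed by the
protocol being emulated.  The same construction with ellipsoids yields
small-3D phantoms (used in smoke tests only; reconstruction is 2D).

Each dataset sample carries the noise-free mean sinogram scaled to the
high-count level and one Poisson realisation of the mean scaled to the
low-count level.  Seeds are drawn per sample from a master generator, so
datasets are bit-reproducible and phantom shape, lesion placement and
noise can be varied independently.

### Count levels at desk scale

The nominal count levels are 500k (low) and 100M (high) for a full-scale
172×172 reconstruction.  What controls both the reconstruction noise and
the operating point of the fusion (see below) is the count *density* —
counts per image pixel — not the total.  Desk-scale studies therefore use
`desk_counts(grid, level) = level · n_pixels / 172²` (≈ 17.3k / 3.46M on a
32×32 grid), which preserves the per-pixel statistics of the full-scale
setting.  The generator's defaults keep the absolute 500k/100M totals; the
scaler itself is exact to 1e−9 at any level.

### Intensity scale of targets

EM reconstructions live on the scale of their data, so a low-count
reconstruction and a high-count reconstruction of the same phantom differ
by the ratio of count levels.  Training targets are therefore computed by
reconstructing the noise-free mean brought to the *low-count* scale, which
is identical to rescaling the high-count reconstruction and keeps network
inputs and targets on one intensity scale.  Evaluations against ground
truth use the phantom multiplied by the sample's low-count scale factor.

## Reconstruction

`poisson_loglik` evaluates `Σ y ln ȳ − ȳ − ln(y!)` with a log-gamma term,
so values are comparable across data; MLEM asserts its monotone increase
every iteration.  OSEM records every subset update ("module") in its
trajectory; with one subset it reduces to MLEM exactly.

The fusion solves, per pixel, `max_{x≥0} x_EM ln x − x − (x−x_Reg)²/(2γs)`.
Of the two algebraically equivalent root formulas, the rationalised form
`2 x_EM / (b + √(b² + 4x_EM/(γs)))` with `b = 1 − x_Reg/(γs)` is used when
`b ≥ 0` and the expanded form `γs(√(b²+4x_EM/(γs)) − b)/2` when `b < 0`,
avoiding cancellation in either regime.  At `x_EM = 0` both branches give
the boundary maximiser `max(x_Reg − γs, 0)` without special-casing.  The
closed form is verified against an independent bracketed 1-D root of the
stationarity condition on 1000 random tuples to ≤ 1e−8 relative.  With
`γ = ∞` the formula evaluates exactly to `x_EM` in IEEE arithmetic, a
property the MAP-EM baseline exploits.

MAP-EM with a quadratic prior performs the gradient step
`x_Reg = x − γβ∇R(x)` with `∇R(x) = 2x` (a pairwise-quadratic smoothness
gradient is available behind a flag, since "Tikhonov" is used ambiguously
in imaging) and then fuses with proximal weight `γ_f = γ/(2β)`.  Tying the
proximal weight to β makes the update continuous in β and *exactly* OSEM
at β = 0 (γ_f = ∞); with a β-independent weight, β = 0 would give a damped
EM step instead, which is neither OSEM nor useful as a baseline anchor.

Both the EM update and the fusion use the *subset* sensitivity, which is
what makes one module a consistent surrogate maximisation for its subset;
a strict mode switches to the global sensitivity for comparison.

## The unrolled network

The regulariser is a residual CNN: five convolutional layers with 32
kernels of 3×3 (3×3×3 in 3D), batch normalisation and ReLU after layers
1–4, and a linear single-channel output layer (≈ 28.6k parameters at 32
channels).  The residual connection is the subtraction in the
regularisation step itself, `x_Reg = x − γ·F(x; θ)`; an optional internal
skip (`F(x) = x + stack(x)`) exists behind a flag.  The final layer is
zero-initialised so an untrained chain starts in a purely classical
regime; other layers are He-initialised under the run seed.

The regularisation-strength product of step size and prior weight is not
identifiable separately from the network's output scale, so the prior
weight is fixed at 1 and absorbed into the final layer; γ remains a
separate trainable scalar, softplus-parameterised (positivity) and
initialised at 0.5.  With iteration-dependent networks each of the
`N_iters × N_subsets` modules (10 × 6 = 60 by default) owns its θⁿ and γⁿ;
with sharing enabled all modules literally reference one parameter set.

Note on the operating point: the fusion weighs the likelihood against the
proximal pull as `γ s_j` versus the image magnitude.  At full scale the
image values are small relative to `γ s`, so an untrained chain is close
to OSEM; the desk-scale count-density scaling above preserves this
regime.

## Training

Targets: module k's target is iterate k of a deterministic 10×6 OSEM
reconstruction of the noise-free data (PSF 2.5 mm in the model), on the
low-count intensity scale.  Optimiser: Adam, MSE loss; defaults lr 0.01,
50 epochs, mini-batch 5 (2D) and lr 0.005, 100 epochs, batch 1 (3D).

- **end_to_end_final** — one loss on the last module against the final
  target, backpropagated through all modules (the shared-regulariser
  formulation trains this way).
- **end_to_end_IS** — the unweighted sum of one MSE term per module, each
  against its own target.
- **sequential_IS** — for n = 1…N: run the frozen prefix in inference
  mode with no tape, optimise module n against target n (each module gets
  the full epoch budget by default; configurable), then freeze it.  Frozen
  parameters are bit-for-bit untouched.  An activation ledger counts array
  elements retained on the autodiff tape per optimisation step; its peak
  is one module's worth, independent of chain depth, whereas end-to-end
  training retains all modules (the measured ratio for a 60-module chain
  is ≈ 62×, a ≈ 98% reduction).
- **leapfrog** — a k-module chain trained on the final (deepest) target
  only; reported with its factor `n_targets/k`, and identical to
  end_to_end_final at k = n_targets.

Batch normalisation uses batch statistics during training (with batch
size 1 this degenerates to per-instance normalisation) and running
averages at inference.  When a module is frozen (sequential) or an epoch
ends (end-to-end), the running averages are pinned to the exact statistics
of one pass over the full training set: with few optimisation steps,
momentum-decayed averages lag the data distribution and inference-mode
forwards (the frozen prefix, test time) would otherwise diverge from the
behaviour training optimised.  For a 1-module chain, one epoch, and a
fixed seed, all regimes perform the identical sequence of floating-point
operations and produce bit-identical parameters — asserted in the tests.

Model selection in end-to-end training keeps the best-validation
checkpoint (final-module MSE on the validation set).

## The iterative-NN baseline

A denoising pass and a reconstruction pass alternate, starting from 10
MLEM iterations.  The denoiser is a two-layer convolutional
encoder-decoder with K = 78 kernels and per-channel learned
soft-thresholds `T(u, α) = sign(u)·max(|u| − e^{−α}, 0)`, α initialised at
15; inputs and outputs are neither normalised nor rescaled.  A
residual-CNN variant reuses the unrolled network's regulariser
architecture as `x − F(x)`.  The reconstruction update is the exact
positive root of the penalised EM surrogate
`β x² + (s − β x_Reg) x − V = 0` with `V_j = x_j [Pᵀ(y ⊘ ȳ)]_j`, evaluated
with a stable branch choice on the sign of `λ = (s − β x_Reg)/(2β)` and
verified against a numeric root; β = 0 reduces exactly to EM.  The penalty
strength is adaptive,
`β = c‖s − Pᵀ(y ⊘ ȳ)‖₂ / ‖x − x_Reg‖₂` with c = 0.05 (capped at 1e6 when
the denominator vanishes), recomputed every outer iteration at train and
test time.  Denoisers are iteration-dependent and trained sequentially
against the final noise-free-data reconstruction; no projector appears in
the denoiser training step.

## Evaluation

NRMSE = RMSE / (mean of the target dataset).  Per-module curves report the
MSE of every module output against (A) the final target and (B) its own
target, with mean ± SD aggregation across runs.  The bias/SD study
reconstructs S independent Poisson realisations (no subsets), and against
the ground-truth phantom — not the high-count reconstruction — computes

    bias² = Σ_Ω (x̄ − ref)² / Σ_Ω ref²,
    SD²   = (1/S) Σ_s Σ_Ω (x^(s) − x̄)² / Σ_Ω ref²,

with Ω defaulting to the activity support.  The ensemble form of SD is
used deliberately so that RMSE² = bias² + SD² holds as an exact algebraic
identity (checked to 1e−10 on every record).  The desk-scale study uses
S = 20 realisations on a 32×32 grid with module counts {10, 20, 40, 60};
assertions are trend-level (bias non-increasing, SD non-decreasing).

## Numerical and reproducibility choices

- All computation is float64; training is bit-reproducible under fixed
  seeds and a fixed BLAS thread count.
- The autodiff engine is a minimal reverse-mode tape over numpy with an
  n-dimensional convolution primitive and sparse-matrix products; every
  operator is validated against central finite differences.
- Seeds are namespaced (normalisation / data / network / training) so
  ablations vary one source of randomness at a time; all sub-seeds stay
  below 2³¹.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the method is examined
on — piecewise-constant anatomy, Poisson counts, attenuation,
normalisation, PSF blur — but not cortical folding, scatter/randoms
physics, detector gaps, or real scanner geometry.  Desk-scale problem
sizes (32×32 grids, 12-module chains, 16 training phantoms, 2 epochs per
module) were chosen so the full pipeline, including three training runs,
executes in about a minute; conclusions at this scale are directional
(the learned chain beats unregularised OSEM; sequential training is
depth-independent in memory), not quantitative claims about clinical
data.  Parameter counts of the full-scale configuration are reported by
the code rather than asserted, and the MAP-EM β values appropriate for
other data scales are not transferable.
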