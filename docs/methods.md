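# Methods

## Forward model

For echo time `t_j` (8 echoes, first echo 4.5 ms, spacing 5 ms, 3 T) the
complex voxel signal is

```
S_j = S0 · exp(−R2 · t_j) · F_bold(Y, v, chi_n, t_j)
         · exp( i · omega0 · t_j · 1e−9 · (d ∗ chi) )
```

with the mesoscopic qBOLD envelope

```
F_bold = exp( −v · fs( delta_omega · t_j ) )
delta_omega = (1/3) · gamma · B0 · 1e−9 · ( pd · (1 − Y) + chi_ba − chi_n )
pd = psi_Hb · dchi_Hb = 1138.25 ppb
```

and the phase governed by the k-space dipole convolution `d ∗ chi` of the
QSM susceptibility model

```
chi = [ chi_ba / alpha + pd · (1 − Y − (1 − alpha) · Ya) / alpha ] · v
      + (1 − v / alpha) · chi_n .
```

Five parameter maps are estimated per voxel: proton-density scaling `S0`,
transverse relaxation rate `R2` (1/s), venous oxygen saturation `Y`,
deoxygenated blood volume fraction `v`, and non-blood susceptibility
`chi_n` (ppb). The oxygen extraction fraction is `OEF = 1 − Y / Ya`.

Physiological constants: `gamma = 267.51e6 rad/s/T`, `psi_Hb = 0.0909`,
`dchi_Hb = 12522 ppb`, `chi_ba = −108.3 ppb`, `Hct = 0.357`,
`alpha = 0.77` (venous fraction of the deoxygenated blood volume),
`Ya = 0.98` (arterial saturation).

### Static-dephasing function `fs`

`fs(x) = (1/3) ∫₀¹ (2+u) √(1−u) (1 − J₀(1.5 x u)) / u² du` is the decay
exponent of a randomly oriented cylinder network in the static dephasing
regime. It is even, `fs(0) = 0`, behaves as `0.3 x²` for small `|x|` and
approaches unit slope for large `|x|`. Numerically the substitution
`u = 1 − s²` removes the endpoint singularity; the integral is evaluated
with 256-node Gauss–Legendre quadrature and memoized as a cubic spline on
`[0, 60]` (knot spacing 0.0025 below 0.5, 0.025 above) with clamped
boundary derivatives `f'(0) = 0` (evenness) and `f'(60) = 1` (asymptote).
The dense small-`x` knots and the derivative clamp keep the *relative*
error of the `0.3 x²` region below 0.4%; a natural spline would be off by
tens of percent near zero because its zero second-derivative boundary
condition contradicts the quadratic behaviour. The test suite checks the
spline against an independent `scipy.integrate.quad` oracle of the
original integrand.

### Dipole convolution

`D(k) = 1/3 − (k·b)²/|k|²` with `D(0) = 0` removes the mean field. The
kernel is real, even and self-adjoint, so gradients of convolution terms
propagate through a second FFT with the same kernel. Uniform
susceptibility therefore produces exactly zero field, and the FFT
convolution matches an explicit DFT sum to machine precision.

## Phantom generator

Synthetic brains are ellipsoidal masks filled with Gaussian-random-field
tissue maps: white noise smoothed by a Gaussian kernel, rescaled to target
population mean/SD per parameter, then clipped to physical ranges
(clipping moves < 1% of voxels at the default smoothness, so sample
moments stay within a few tenths of a percent of the targets). Each
phantom carries an elliptical low-`Y` "lesion" and a mirrored
contralateral ROI. A margin of one-quarter grid size separates the mask
from the volume boundary so the periodic FFT dipole convolution does not
wrap tissue field into the mask.

Two noise models are provided:

* **complex Gaussian** — i.i.d. `N(0, σ²)` on real and imaginary parts of
  every echo, `σ = mean(|S_1|) · 10^(−SNR_dB/20)` over the mask; this is
  the physically correct thermal-noise model of a coil-combined
  gradient-echo acquisition;
* **magnitude + susceptibility Gaussian** — Gaussian on echo magnitudes
  (the standard qBOLD assumption, which ignores the Rician floor) plus
  Gaussian noise (default SD 10 ppb) on a pre-computed susceptibility map,
  mimicking a conventional QSM+qBOLD pipeline where phase information is
  collapsed into a reconstructed `chi` map before fitting.

## Inversion

Per-voxel maximum-likelihood fitting proceeds in three stages:

1. **variable-projection magnitude sweep** — on a coarse grid over
   `(Y, v)` the magnitude model is linear in `(log S0, R2)` after taking
   logs, so those are projected out in closed form; the best grid cell
   initializes the nonlinear refinement. This removes most local-minimum
   failures of the notoriously flat qBOLD likelihood.
2. **linear MAP update of `(Y, chi_n)`** from the field/susceptibility
   data (the susceptibility model is linear in both given `v`), solved by
   LSMR with an uncertainty weight on `delta_omega` propagated from the
   magnitude stage.
3. **bounded Levenberg–Marquardt** on all five parameters, batched over
   voxels, with Marquardt scaling (`λ · diag(JᵀJ)`) and a smooth bound
   parametrization. For the joint complex fit the dipole convolution
   couples voxels, so the LM step is computed matrix-free with LSMR and a
   discrepancy-principle stopping rule.

Three estimators share this machinery: `fit_mcqq_joint` (complex data,
field generated self-consistently from the candidate maps),
`fit_mcqq_oracle_field` (complex data with a known tissue field, plus an
optional susceptibility prior) and `fit_qq_baseline` (Gaussian likelihood
on magnitudes and a measured susceptibility map — the conventional
QSM+qBOLD objective).

Because the likelihood is degenerate in parts of parameter space, the
coarse-sweep stage can have near-tied candidates; under floating-point
rescaling of the data these ties may flip and seed different local basins
in a handful of voxels. Gauge equivariance (scaling data, `S0` bounds and
`σ` together) therefore holds exactly along a common optimization path but
only statistically across paths.

## Network

A dual 3-D U-Net implemented from scratch in NumPy with analytic
gradients (every layer and loss is finite-difference checked):

* two identical sub-networks take 8 z-scored echo magnitudes and 8 tissue
  phases respectively; each level applies two 3×3×3 convolutions + ReLU,
  with 2³ max-pooling down and 2³ transposed-convolution up plus skip
  concatenation, and a final 1×1×1 convolution (at depth 4: 18 conv3, 4
  pool, 4 deconv, 4 concat, 1 conv1 per sub-network);
* the magnitude branch predicts all five parameters, the phase branch
  predicts `(Y, v, chi_n)`; shared channels are merged by learnable
  per-channel weights (initialized 0.5/0.5) before a tanh squashing onto
  the open physical intervals;
* loss `E = E_L1 + 0.1·E_model + 0.1·E_grad`: masked mean absolute error
  on z-scored parameters, a model-consistency term (complex signal
  mismatch through the full forward model for the mcQQ variant — using a
  patch-local dipole kernel, a deliberate approximation of the
  whole-volume convolution — or magnitude + susceptibility mismatch for
  the QQ variant), and a forward-difference gradient-matching term;
* Adam on single-patch batches; per-epoch noise, brain order and patch
  positions are re-drawn from `default_rng(seed + epoch)`, so training is
  bit-reproducible. An optional frozen validation batch provides a loss
  history that is exactly constant at `lr = 0` (the training history is
  not, because the data are re-sampled every epoch by design). Any
  non-finite loss or gradient aborts training with a diagnostic.

Inference uses sliding windows with configurable overlap and uniform
averaging; volumes smaller than the patch are zero-padded. Inputs are
z-scored per volume, so a constant input volume enters the network as
zeros and — for freshly initialized networks, whose biases are zero —
produces a constant output (the bound midpoints). Trained networks have
nonzero biases, so zero-padding at the borders can break exact constancy.

## Evaluation

Accuracy and precision over repeated noise trials are summarized by the
mean error and mean per-voxel SD (population divisor) over the mask,
lesion/contralateral OEF ratio, masked SSIM, and an exact (n ≤ 25)
Wilcoxon signed-rank test with normal approximation and continuity
correction beyond.

## Limitations

* Desk scale only: grids up to ~48³ and minute-scale training runs; no
  GPU, no data augmentation, no real-data preprocessing (coil combination,
  unwrapping and background-field removal are assumed done; `mcqq.io`
  provides only the final phase/magnitude compensation step).
* The static-dephasing envelope assumes randomly oriented cylinders and
  ignores diffusion narrowing at short echo times.
* The joint fit's advantage over the magnitude baseline is demonstrated on
  matched synthetic data where each estimator sees its own noise model; it
  is a statement about noise-model information content, not about
  robustness to model mismatch.
* The model-consistency training loss evaluates the dipole convolution on
  the training patch, not the whole volume; long-range field contributions
  from outside the patch are neglected.
* OEF is reported relative to a fixed arterial saturation `Ya = 0.98`;
  individual variation in `Ya`, hematocrit or vessel geometry biases the
  absolute scale.
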