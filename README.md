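# mcqq

Joint QSM + qBOLD estimation of the oxygen extraction fraction (OEF) from
multi-echo gradient-echo MRI, fitted directly in the **complex** signal
domain.

Classical quantitative BOLD (qBOLD) fits the echo-magnitude decay, and
quantitative susceptibility mapping (QSM) inverts the phase-derived field
map for tissue susceptibility; combining the two (QSM+qBOLD, "QQ")
disentangles venous oxygenation `Y` from the deoxygenated blood volume
fraction `v`. This package implements a multi-echo **complex**-domain
variant: the forward model predicts each echo's complex value — a qBOLD
magnitude envelope times a phase accrued by the dipole-convolved
susceptibility field — and the inversion fits magnitude and phase jointly
under the physically correct complex Gaussian noise model, instead of
fitting Rician magnitudes and a separately reconstructed susceptibility map
with assumed Gaussian errors.

## What is in the box

| module | contents |
| --- | --- |
| `mcqq.biophysics` | forward signal model: qBOLD envelope with the static-dephasing function `fs`, venous susceptibility `chi_qsm`, k-space dipole kernel, field/phase synthesis, physiological constants |
| `mcqq.phantom` | seeded synthetic brains (smooth `S0, R2, Y, v, chi_n` maps, elliptical lesion/contralateral ROIs) and the two noise models (complex Gaussian; magnitude + susceptibility Gaussian) |
| `mcqq.inversion` | per-voxel maximum-likelihood fits: `fit_mcqq_joint` (complex data, self-consistent dipole field), `fit_mcqq_oracle_field` (complex data, known field) and `fit_qq_baseline` (magnitude + susceptibility map), all with staged initialization and bounded Levenberg–Marquardt |
| `mcqq.network` | a from-scratch NumPy dual 3-D U-Net (magnitude branch + phase branch) trained with an L1 + model-consistency + gradient loss, with analytic gradients throughout, plus sliding-window prediction |
| `mcqq.metrics` | evaluation: mean error / mean SD over repeated trials, lesion/contralateral OEF ratio, masked SSIM, exact Wilcoxon signed-rank test |
| `mcqq.io` | phase/magnitude pre-compensation, NIfTI round trips for signal stacks and parameter maps, run configs with content hashes, network checkpoints |
| `mcqq.cli` | `mcqq simulate / fit / train / predict / evaluate` |

## Worked example

Simulate a synthetic brain, add complex noise at 25 dB SNR, and fit the
five parameter maps jointly from the complex echoes:

```python
import numpy as np
from mcqq import (AcquisitionParams, PhysioConstants, FitConfig,
                  PhantomConfig, NoiseSpec, add_complex_noise,
                  fit_mcqq_joint, make_phantom, noise_sigma,
                  oef_from_Y, simulate_signal)

consts = PhysioConstants()
acq = AcquisitionParams(grid_shape=(24, 24, 24))   # 8 echoes, TE1 4.5 ms

# synthetic brain: smooth tissue maps plus an elliptical low-Y lesion
truth, lesion, contra = make_phantom(PhantomConfig(grid_shape=(24, 24, 24), seed=3))
signal = simulate_signal(truth, acq, consts)        # complex, 8 echoes
noisy = add_complex_noise(signal, NoiseSpec(snr_db=25.0, seed=0), truth.mask)

cfg = FitConfig(init="truth_perturbed", init_maps=truth, perturb_frac=0.1,
                seed=1, max_iter=60)
result = fit_mcqq_joint(noisy, acq, consts, cfg, truth.mask)

m = truth.mask
oef_true = oef_from_Y(truth.Y[m], consts.Ya)
oef_fit = result.oef[m]
print(f"voxels fitted     : {m.sum()}")
print(f"true mean OEF     : {oef_true.mean():.4f}")
print(f"fitted mean OEF   : {oef_fit.mean():.4f}")
print(f"OEF RMSE          : {np.sqrt(np.mean((oef_fit - oef_true) ** 2)):.4f}")
print(f"objective trace   : {result.objective_trace[0]:.1f} -> {result.objective_trace[-1]:.1f}")
```

Output (exact, seeded):

```
voxels fitted     : 912
true mean OEF     : 0.3163
fitted mean OEF   : 0.3156
OEF RMSE          : 0.0499
objective trace   : 61.4 -> 42.6
```

The same pipeline is available from the command line:

```bash
mcqq simulate --seed 3 --grid 24 --snr-db 25 --out run/sim
mcqq fit --mode mcqq_joint --signal run/sim/signal \
         --mask run/sim/truth_mask.nii --out run/fit
mcqq evaluate --truth run/sim/oef_true.nii --trial run/fit/oef.nii \
              --mask run/sim/truth_mask.nii --out run/eval
```

Every command writes a resolved YAML config (with a content hash) next to
its outputs, and all outputs are bit-reproducible for a fixed seed.

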