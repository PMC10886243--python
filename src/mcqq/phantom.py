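"""Synthetic stroke-brain phantom and noise injectors.

The generator emulates the training-data conditions of the signal model:
spatially smooth 3-D parameter fields (S0, R2, Y, v, chi_n) whose within-mask
statistics reproduce the stroke-cohort values

    S0    mean 1.10,  SD 0.04,  range [1.04, 2.12]
    R2    mean 19.6,  SD 7.1,   range [7.3, 161.1]   (1/s)
    Y     mean 0.67,  SD 0.10,  range [0.31, 0.98]
    v     mean 0.023, SD 0.012, range [0.003, 0.072]
    chi_n mean -11.6, SD 37.5,  range [-957.2, 159.7] (ppb)

inside an ellipsoidal brain, with an ellipsoidal ischemic lesion in which Y
and v are reduced (subacute low-OEF, low blood volume phenotype) and a
contralateral mask mirrored across the mid-sagittal plane.  Complex Gaussian
noise is calibrated to a stated first-echo SNR in dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .biophysics import ComplexSignalStack, ParameterMaps

__all__ = [
    "TISSUE_STATS",
    "PhantomConfig",
    "NoiseSpec",
    "make_phantom",
    "add_complex_noise",
    "add_magnitude_qsm_noise",
    "noise_sigma",
]

# per-parameter (mean, sd, min, max) targets of the generator
TISSUE_STATS = {
    "S0": (1.10, 0.04, 1.04, 2.12),
    "R2": (19.6, 7.1, 7.3, 161.1),
    "Y": (0.67, 0.10, 0.31, 0.98),
    "v": (0.023, 0.012, 0.003, 0.072),
    "chi_n": (-11.6, 37.5, -957.2, 159.7),
}


@dataclass
class PhantomConfig:
    """Configuration of the synthetic stroke brain.

    The brain is an ellipsoid filling half of each grid dimension (so a >=25%
    zero margin remains on every side for the circular dipole convolution).
    ``lesion_center`` and ``lesion_radii`` are in fractions of the grid;
    ``smoothness`` is the Gaussian correlation length in mm.
    """

    grid_shape: tuple = (48, 48, 48)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    seed: int = 0
    lesion_center: tuple = (0.62, 0.5, 0.5)   # fractional grid coordinates
    lesion_radii: tuple = (0.10, 0.10, 0.10)  # fractional grid radii
    lesion_Y_scale: float = 0.6
    lesion_v_scale: float = 0.5
    tissue_stats: dict = field(default_factory=lambda: dict(TISSUE_STATS))
    smoothness: float = 6.0

    def __post_init__(self) -> None:
        for name, (mu, sd, lo, hi) in self.tissue_stats.items():
            if not (lo <= mu <= hi):
                raise ValueError(f"{name}: need min <= mean <= max, got {lo}, {mu}, {hi}")
            if sd <= 0:
                raise ValueError(f"{name}: sd must be positive")


@dataclass
class NoiseSpec:
    """Noise model and level: SNR at the first echo in dB (amplitude ratio)."""

    snr_db: float = 20.0
    model: str = "complex_gaussian"
    seed: int = 0
    sigma_chi: float = 10.0  # ppb; susceptibility noise SD for the baseline model

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")
        if self.model not in ("complex_gaussian", "magnitude_plus_qsm_gaussian"):
            raise ValueError(f"unknown noise model {self.model!r}")


def _ellipsoid_mask(grid_shape, center_frac, radii_frac) -> np.ndarray:
    idx = np.indices(grid_shape).astype(float)
    dist2 = np.zeros(grid_shape)
    for ax, n in enumerate(grid_shape):
        c = center_frac[ax] * (n - 1)
        r = max(radii_frac[ax] * n, 1e-9)
        dist2 += ((idx[ax] - c) / r) ** 2
    return dist2 <= 1.0


def _smooth_field(rng, grid_shape, sigma_vox) -> np.ndarray:
    """Gaussian-filtered white noise, rescaled to unit variance."""
    z = gaussian_filter(rng.standard_normal(grid_shape), sigma_vox, mode="wrap")
    return z / z.std()


def _calibrated_field(rng, grid_shape, mask, sigma_vox, mu, sd, lo, hi,
                      post=None, n_iter: int = 20) -> np.ndarray:
    """Smooth random field whose final within-mask mean/SD hit (mu, sd).

    Clipping to [lo, hi] (and any ``post`` transform, e.g. lesion scaling)
    biases the sample moments, so the pre-clip location and scale are
    adjusted by fixed-point iteration on the post-transform statistics.
    The mask statistics are measured after ``post``; ``post`` receives and
    returns the full 3-D map and must preserve the [lo, hi] bounds.
    """
    z = _smooth_field(rng, grid_shape, sigma_vox)
    z = (z - z[mask].mean()) / z[mask].std()
    loc, scale = mu, sd

    def realize(loc, scale):
        x = np.clip(loc + scale * z, lo, hi)
        return post(x) if post is not None else x

    for _ in range(n_iter):
        xm = realize(loc, scale)[mask]
        m, s = xm.mean(), xm.std()
        loc += mu - m
        scale *= sd / max(s, 1e-12)
    return realize(loc, scale)


def make_phantom(config: PhantomConfig):
    """Generate (ParameterMaps, lesion_mask, contralateral_mask).

    Deterministic in ``config.seed``.  Lesion voxels have Y and v multiplied
    by the configured scales and re-clipped to the parameter bounds; the
    contralateral mask is the lesion mask mirrored across the mid-sagittal
    plane (first grid axis).
    """
    grid = tuple(int(n) for n in config.grid_shape)
    rng = np.random.default_rng(config.seed)
    # brain ellipsoid: semi-axes 1/4 of each dimension => >=25% margin
    brain = _ellipsoid_mask(grid, (0.5, 0.5, 0.5), (0.25, 0.25, 0.25))
    lesion = _ellipsoid_mask(grid, config.lesion_center, config.lesion_radii)
    if np.any(lesion & ~brain):
        raise ValueError("lesion extends outside the brain ellipsoid")
    contra = lesion[::-1, :, :].copy()

    sigma_vox = np.asarray(config.smoothness, float) / np.asarray(config.voxel_size, float)
    sigma_vox = np.broadcast_to(sigma_vox, (3,))
    # subacute ischemic lesion: reduced venous oxygenation and blood volume;
    # applied inside the calibration loop so the whole-mask statistics
    # (which, in the source cohort, include lesions) hit their targets
    lesion_scales = {"Y": config.lesion_Y_scale, "v": config.lesion_v_scale}

    maps = {}
    for name in ParameterMaps.PARAM_NAMES:
        mu, sd, lo, hi = config.tissue_stats[name]
        post = None
        if name in lesion_scales:
            scale = lesion_scales[name]

            def post(x, _s=scale, _lo=lo, _hi=hi):
                return np.where(lesion, np.clip(x * _s, _lo, _hi), x)

        maps[name] = _calibrated_field(rng, grid, brain, sigma_vox, mu, sd, lo, hi, post=post)

    for name in ParameterMaps.PARAM_NAMES:
        maps[name] = np.where(brain, maps[name], 0.0)

    params = ParameterMaps(mask=brain, **maps)
    return params, lesion, contra


def noise_sigma(signal: ComplexSignalStack, mask: np.ndarray, snr_db: float) -> float:
    """Per-channel noise SD for a target first-echo SNR in amplitude dB.

    SNR_dB = 20 log10(signal/sigma) with signal the mask-mean first-echo
    magnitude.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    s1 = np.abs(signal.data[0])[mask].mean()
    return float(s1 * 10.0 ** (-snr_db / 20.0))


def add_complex_noise(signal: ComplexSignalStack, spec: NoiseSpec,
                      mask: np.ndarray | None = None) -> ComplexSignalStack:
    """Add i.i.d. zero-mean Gaussian noise to real and imaginary channels.

    The common SD sigma is set from ``spec.snr_db`` at the first echo.
    """
    if spec.model != "complex_gaussian":
        raise ValueError("spec.model must be 'complex_gaussian'")
    if mask is None:
        mask = np.abs(signal.data[0]) > 0
    sigma = noise_sigma(signal, mask, spec.snr_db)
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(signal.data.shape) + 1j * rng.standard_normal(signal.data.shape)
    return ComplexSignalStack(signal.data + sigma * noise, signal.acq)


def add_magnitude_qsm_noise(magnitudes: np.ndarray, chi_map: np.ndarray,
                            spec: NoiseSpec, mask: np.ndarray | None = None):
    """Gaussian noise on echo magnitudes and on the susceptibility map.

    This is the baseline noise model that treats both the mGRE magnitude and
    the susceptibility as Gaussian-corrupted.  Magnitude noise uses the same
    first-echo-SNR sigma convention as the complex model; noisy magnitudes
    can go negative (Gaussian, not Rician) — an intentional property of this
    baseline.  The chi noise SD defaults to 10 ppb and is configurable via
    ``spec.sigma_chi``.
    """
    if spec.model != "magnitude_plus_qsm_gaussian":
        raise ValueError("spec.model must be 'magnitude_plus_qsm_gaussian'")
    magnitudes = np.asarray(magnitudes, dtype=float)
    if mask is None:
        mask = magnitudes[0] > 0
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    s1 = magnitudes[0][mask].mean()
    sigma = s1 * 10.0 ** (-spec.snr_db / 20.0)
    sigma_chi = spec.sigma_chi
    rng = np.random.default_rng(spec.seed)
    noisy_mag = magnitudes + sigma * rng.standard_normal(magnitudes.shape)
    noisy_chi = np.asarray(chi_map, float) + sigma_chi * rng.standard_normal(chi_map.shape)
    return noisy_mag, noisy_chi
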