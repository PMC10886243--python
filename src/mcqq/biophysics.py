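"""Forward biophysical model linking tissue parameters to complex mGRE signals.

The model combines two views of the paramagnetic effect of deoxyhemoglobin on
a multi-echo gradient-echo (mGRE) acquisition:

* a qBOLD magnitude model — static-dephasing signal decay from a network of
  randomly oriented venous vessels, on top of mono-exponential R2 decay; and
* a QSM phase model — the voxel susceptibility is split into a venous-blood
  deoxyhemoglobin contribution (the OEF effect) and the non-blood neural
  tissue susceptibility ``chi_n``, and the induced tissue field follows from
  dipole convolution.

The five voxel-wise unknowns are ``S0`` (signal at t = 0), ``R2`` (1/s),
venous oxygenation ``Y`` (fraction), venous blood volume fraction ``v`` and
``chi_n`` (ppb).  Oxygen extraction fraction is ``OEF = 1 - Y / Ya``.

All susceptibilities are carried in ppb; the single 1e-9 conversion happens
inside :func:`delta_omega` and inside the phase term of
:func:`simulate_signal`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import j0

__all__ = [
    "PhysioConstants",
    "AcquisitionParams",
    "ParameterMaps",
    "ComplexSignalStack",
    "delta_omega",
    "fs",
    "fs_quadrature",
    "f_bold",
    "f_qbold",
    "chi_qsm",
    "chi_qsm_mixture",
    "dipole_kernel",
    "chi_from_field",
    "field_from_chi",
    "simulate_signal",
    "oef_from_Y",
]

PPB = 1e-9


@dataclass(frozen=True)
class PhysioConstants:
    """Fixed physiological/physical constants of the signal model.

    Attributes
    ----------
    gamma : float
        Proton gyromagnetic ratio, rad s^-1 T^-1.
    psi_Hb : float
        Hemoglobin volume fraction (dimensionless, at Hct = 0.357).
    dchi_Hb : float
        Susceptibility difference between deoxy- and oxyhemoglobin, ppb.
    chi_ba : float
        Susceptibility of fully oxygenated blood, ppb.
    Hct : float
        Tissue hematocrit (dimensionless).
    alpha : float
        Ratio of venous to total blood volume.
    Ya : float
        Arterial oxygenation (fraction).
    """

    gamma: float = 267.51e6
    psi_Hb: float = 0.0909
    dchi_Hb: float = 12522.0
    chi_ba: float = -108.3
    Hct: float = 0.357
    alpha: float = 0.77
    Ya: float = 0.98

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 < self.Ya <= 1.0):
            raise ValueError(f"Ya must be in (0, 1], got {self.Ya}")
        if self.psi_Hb <= 0 or self.dchi_Hb <= 0:
            raise ValueError("psi_Hb and dchi_Hb must be positive")


@dataclass(frozen=True)
class AcquisitionParams:
    """Echo times and field geometry of the mGRE protocol.

    Defaults follow the 3 T protocol with eight equally spaced echoes,
    TE1/dTE/TE8 = 4.5/5/39.5 ms.
    """

    echo_times: tuple = tuple(0.0045 + 0.005 * j for j in range(8))
    B0: float = 3.0
    B0_dir: tuple = (0.0, 0.0, 1.0)
    voxel_size: tuple = (1.0, 1.0, 1.0)
    grid_shape: tuple = (32, 32, 32)

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.ndim != 1 or len(te) == 0:
            raise ValueError("echo_times must be a non-empty 1-D sequence")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be positive and strictly increasing")
        b = np.asarray(self.B0_dir, dtype=float)
        if not np.isclose(np.linalg.norm(b), 1.0):
            raise ValueError("B0_dir must be a unit vector")
        if np.any(np.asarray(self.voxel_size, dtype=float) <= 0):
            raise ValueError("voxel_size must be positive")

    def omega0(self, consts: PhysioConstants | None = None) -> float:
        """Larmor angular frequency gamma * B0, rad/s."""
        consts = consts or PhysioConstants()
        return consts.gamma * self.B0


@dataclass
class ParameterMaps:
    """Co-registered 3-D maps of the five model unknowns plus brain mask.

    Values outside the mask are zero-filled so the dipole convolution is
    well-posed on the full grid.
    """

    S0: np.ndarray
    R2: np.ndarray
    Y: np.ndarray
    v: np.ndarray
    chi_n: np.ndarray
    mask: np.ndarray

    PARAM_NAMES = ("S0", "R2", "Y", "v", "chi_n")

    def __post_init__(self) -> None:
        shape = self.S0.shape
        for name in (*self.PARAM_NAMES, "mask"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"map {name!r} has shape {arr.shape}, expected {shape}")
        self.mask = self.mask.astype(bool)
        m = self.mask
        if np.any(self.Y[m] < 0) or np.any(self.Y[m] > 1):
            raise ValueError("Y must lie in [0, 1] inside the mask")
        if np.any(self.v[m] < 0):
            raise ValueError("v must be non-negative inside the mask")
        if np.any(self.S0[m] < 0) or np.any(self.R2[m] < 0):
            raise ValueError("S0 and R2 must be non-negative inside the mask")

    @property
    def grid_shape(self) -> tuple:
        return self.S0.shape

    def stack(self) -> np.ndarray:
        """Parameter maps stacked along a leading axis, order S0,R2,Y,v,chi_n."""
        return np.stack([getattr(self, n) for n in self.PARAM_NAMES])

    @classmethod
    def from_stack(cls, arr: np.ndarray, mask: np.ndarray) -> "ParameterMaps":
        return cls(*(arr[i] for i in range(5)), mask=mask)


@dataclass
class ComplexSignalStack:
    """Echo-indexed complex 4-D mGRE signal, shape (n_echo, x, y, z)."""

    data: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.acq.echo_times):
            raise ValueError(
                f"echo axis {self.data.shape[0]} does not match "
                f"{len(self.acq.echo_times)} echo times"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_echo(self) -> int:
        return self.data.shape[0]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.data)

    def phase(self) -> np.ndarray:
        return np.angle(self.data)


# ---------------------------------------------------------------------------
# characteristic frequency and static-dephasing decay


def delta_omega(Y, chi_n, consts: PhysioConstants | None = None, B0: float = 3.0):
    """Characteristic frequency offset between deoxygenated blood and tissue.

    delta_omega = (1/3) * gamma * B0 * (psi_Hb * dchi_Hb * (1 - Y)
                                        + chi_ba - chi_n) * 1e-9

    with susceptibilities in ppb.  Returns rad/s; may be negative when
    ``chi_n`` exceeds the blood term.
    """
    consts = consts or PhysioConstants()
    Y = np.asarray(Y, dtype=float)
    chi_n = np.asarray(chi_n, dtype=float)
    if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(chi_n))):
        raise ValueError("delta_omega requires finite inputs")
    susc_ppb = consts.psi_Hb * consts.dchi_Hb * (1.0 - Y) + consts.chi_ba - chi_n
    return (1.0 / 3.0) * consts.gamma * B0 * susc_ppb * PPB


def _fs_integrand_s(s: np.ndarray, x: np.ndarray) -> np.ndarray:
    # substitution u = 1 - s^2 removes the sqrt(1-u) endpoint singularity:
    # fs(x) = (1/3) int_0^1 2 s^2 (3 - s^2) [1 - J0(1.5 x (1-s^2))] / (1-s^2)^2 ds
    u = 1.0 - s * s
    with np.errstate(divide="ignore", invalid="ignore"):
        core = (1.0 - j0(1.5 * x * u)) / (u * u)
    # u -> 0 limit of [1 - J0(1.5 x u)]/u^2 is (1.5 x)^2 / 4
    core = np.where(u < 1e-8, (1.5 * x) ** 2 / 4.0, core)
    return 2.0 * s * s * (3.0 - s * s) * core


@lru_cache(maxsize=4)
def _gl_nodes(n: int):
    return np.polynomial.legendre.leggauss(n)


def _fs_direct(x: np.ndarray, order: int = 256) -> np.ndarray:
    """Gauss-Legendre evaluation of the cylinder-network dephasing integral."""
    nodes, weights = _gl_nodes(order)
    s = 0.5 * (nodes + 1.0)  # map [-1,1] -> [0,1]
    w = 0.5 * weights
    xa = np.atleast_1d(np.abs(np.asarray(x, dtype=float)))
    vals = _fs_integrand_s(s[None, :], xa.reshape(-1, 1))
    out = (vals @ w) / 3.0
    return out.reshape(np.shape(xa))


def fs_quadrature(x: float, order: int = 512) -> float:
    """High-order scalar evaluation of the dephasing integral (slow path)."""
    return float(np.ravel(_fs_direct(np.abs(float(x)), order=order))[0])


_FS_TABLE_MAX = 60.0


@lru_cache(maxsize=1)
def _fs_spline() -> CubicSpline:
    # dense knots near zero keep the relative error of the ~0.3 x^2 region
    # small; evenness fixes f'(0) = 0 and the large-x asymptote has slope 1
    grid = np.concatenate([np.arange(0.0, 0.5, 0.0025),
                           np.linspace(0.5, _FS_TABLE_MAX, 2381)])
    return CubicSpline(grid, _fs_direct(grid), bc_type=((1, 0.0), (1, 1.0)))


def fs(x):
    """Static-dephasing decay exponent of a randomly oriented vessel network.

    Even in its argument, fs(0) = 0, ~ 0.3 x^2 for small |x| and asymptotically
    linear with unit slope for large |x|.  Evaluated from a memoized
    cubic-spline table of the cylinder-orientation integral

        fs(x) = (1/3) int_0^1 (2+u) sqrt(1-u) [1 - J0(1.5 x u)] / u^2 du.
    """
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    scalar = ax.ndim == 0
    ax = np.atleast_1d(ax)
    out = np.empty_like(ax)
    inside = ax <= _FS_TABLE_MAX
    if np.any(inside):
        out[inside] = _fs_spline()(ax[inside])
    if np.any(~inside):
        out[~inside] = _fs_direct(ax[~inside])
    np.maximum(out, 0.0, out=out)
    return float(out[0]) if scalar else out


def fs_prime(x):
    """Derivative of :func:`fs`; odd function (fs is even)."""
    x = np.asarray(x, dtype=float)
    ax = np.abs(x)
    scalar = ax.ndim == 0
    ax = np.atleast_1d(ax)
    out = np.empty_like(ax)
    inside = ax <= _FS_TABLE_MAX
    if np.any(inside):
        out[inside] = _fs_spline()(ax[inside], 1)
    if np.any(~inside):
        # long-time regime: fs'(x) -> 1; use a central difference on the
        # direct evaluation for the rare out-of-table arguments
        h = 1e-3
        out[~inside] = (_fs_direct(ax[~inside] + h) - _fs_direct(ax[~inside] - h)) / (2 * h)
    out = out * np.sign(np.atleast_1d(x))
    return float(out[0]) if scalar else out


def f_bold(Y, v, chi_n, t, consts: PhysioConstants | None = None, B0: float = 3.0):
    """Mesoscopic attenuation exp(-v * fs(delta_omega * t)) in (0, 1]."""
    v = np.asarray(v, dtype=float)
    if np.any(v < 0):
        raise ValueError("v must be non-negative")
    dw = delta_omega(Y, chi_n, consts, B0)
    return np.exp(-v * fs(dw * np.asarray(t, dtype=float)))


def f_qbold(params: ParameterMaps, acq: AcquisitionParams,
            consts: PhysioConstants | None = None, G=None, echo: int | None = None):
    """qBOLD magnitude model S0 exp(-R2 t) F_BOLD G(t).

    Parameters
    ----------
    G : ndarray or None
        Macroscopic-field attenuation factor, shape (n_echo, *grid) or
        broadcastable; values in (0, 1].  Defaults to 1 (synthetic data).
    echo : int or None
        If given, return only that echo's magnitude map; otherwise the full
        (n_echo, x, y, z) stack.
    """
    consts = consts or PhysioConstants()
    te = np.asarray(acq.echo_times, dtype=float)
    echoes = range(len(te)) if echo is None else [echo]
    if G is None:
        G = 1.0
    else:
        G = np.asarray(G, dtype=float)
        if np.any(G <= 0) or np.any(G > 1):
            raise ValueError("G must lie in (0, 1]")
        if G.ndim == 4 and G.shape[1:] != params.grid_shape:
            raise ValueError("G grid does not match parameter maps")
    dw = delta_omega(params.Y, params.chi_n, consts, acq.B0)
    out = []
    for j in echoes:
        t = te[j]
        Gj = G[j] if isinstance(G, np.ndarray) and G.ndim == 4 else G
        out.append(params.S0 * np.exp(-params.R2 * t - params.v * fs(dw * t)) * Gj)
    return out[0] if echo is not None else np.stack(out)


# ---------------------------------------------------------------------------
# susceptibility model and dipole field


def chi_qsm(Y, v, chi_n, consts: PhysioConstants | None = None):
    """Voxel susceptibility (ppb) from venous blood and neural tissue.

    chi = [chi_ba/alpha + psi_Hb*dchi_Hb*(1 - Y - (1-alpha)*Ya)/alpha] * v
          + (1 - v/alpha) * chi_n

    Linear in each of ``v`` and ``chi_n`` separately.  See
    :func:`chi_qsm_mixture` for the three-compartment mixture form, which
    differs slightly in the Y weighting.
    """
    consts = consts or PhysioConstants()
    Y = np.asarray(Y, dtype=float)
    v = np.asarray(v, dtype=float)
    chi_n = np.asarray(chi_n, dtype=float)
    if np.any(v >= consts.alpha):
        raise ValueError("v must be < alpha (non-negative tissue fraction)")
    blood = (consts.chi_ba / consts.alpha
             + consts.psi_Hb * consts.dchi_Hb
             * (1.0 - Y - (1.0 - consts.alpha) * consts.Ya) / consts.alpha)
    return blood * v + (1.0 - v / consts.alpha) * chi_n


def chi_qsm_mixture(Y, v, chi_n, consts: PhysioConstants | None = None):
    """Volume-weighted three-compartment susceptibility mixture (cross-check).

    chi = v*chi_v + v*(1-alpha)/alpha*chi_a + (1 - v/alpha)*chi_n with
    chi_v = chi_ba + psi_Hb*dchi_Hb*(1-Y) and
    chi_a = chi_ba + psi_Hb*dchi_Hb*(1-Ya).
    """
    consts = consts or PhysioConstants()
    Y = np.asarray(Y, dtype=float)
    v = np.asarray(v, dtype=float)
    chi_v = consts.chi_ba + consts.psi_Hb * consts.dchi_Hb * (1.0 - Y)
    chi_a = consts.chi_ba + consts.psi_Hb * consts.dchi_Hb * (1.0 - consts.Ya)
    arterial_frac = (1.0 - consts.alpha) / consts.alpha
    return v * chi_v + v * arterial_frac * chi_a + (1.0 - v / consts.alpha) * chi_n


def dipole_kernel(grid_shape, voxel_size=(1.0, 1.0, 1.0), B0_dir=(0.0, 0.0, 1.0)) -> np.ndarray:
    """k-space unit dipole kernel D(k) = 1/3 - (k.b)^2/|k|^2, with D(0) = 0.

    Frequencies come from the FFT grid scaled by voxel size; ``B0_dir`` is
    applied by projecting k onto it.  Values lie in [-2/3, 1/3].
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    if any(n < 2 for n in grid_shape):
        raise ValueError("grid_shape entries must be >= 2")
    voxel_size = np.asarray(voxel_size, dtype=float)
    if np.any(voxel_size <= 0):
        raise ValueError("voxel_size must be positive")
    b = np.asarray(B0_dir, dtype=float)
    b = b / np.linalg.norm(b)
    ks = [np.fft.fftfreq(n, d=dx) for n, dx in zip(grid_shape, voxel_size)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k2 = kx * kx + ky * ky + kz * kz
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 / 3.0 - (kb * kb) / k2
    D[k2 == 0] = 0.0
    return D


def field_from_chi(chi: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Dipole-convolved tissue field d * chi (same unit as chi, i.e. ppb).

    Computed as IFFT(D . FFT(chi)); circular convolution, so sources must
    keep a zero margin to suppress wrap-around.  A spatially uniform chi
    yields an identically zero field because D(0) = 0.
    """
    chi = np.asarray(chi, dtype=float)
    if chi.shape != kernel.shape:
        raise ValueError(f"chi shape {chi.shape} does not match kernel {kernel.shape}")
    return np.real(np.fft.ifftn(kernel * np.fft.fftn(chi)))


def chi_from_field(field: np.ndarray, kernel: np.ndarray,
                   threshold: float = 0.15) -> np.ndarray:
    """Thresholded k-space dipole inversion (TKD) of a tissue field.

    The inverse filter 1/D is applied where |D| >= ``threshold``; elsewhere
    it is replaced by sign(D)/threshold, the standard truncation that keeps
    the conical null surface of the dipole kernel from amplifying noise
    without bound.  This is the simple susceptibility-mapping step of a
    two-stage magnitude+QSM pipeline; the truncation is what makes such
    pipelines lossy compared to keeping the convolution inside the
    likelihood.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != kernel.shape:
        raise ValueError(f"field shape {field.shape} does not match kernel {kernel.shape}")
    if not 0.0 < threshold < 2.0 / 3.0:
        raise ValueError("threshold must lie in (0, 2/3)")
    Dinv = np.where(np.abs(kernel) >= threshold,
                    1.0 / np.where(kernel == 0.0, np.inf, kernel),
                    np.where(kernel >= 0.0, 1.0, -1.0) / threshold)
    return np.real(np.fft.ifftn(Dinv * np.fft.fftn(field)))


def simulate_signal(params: ParameterMaps, acq: AcquisitionParams,
                    consts: PhysioConstants | None = None, G=None) -> ComplexSignalStack:
    """Noise-free forward model: S_j = F_qBOLD * exp(i w0 t_j (d * F_QSM)).

    The magnitude is the qBOLD model and the phase grows linearly in echo
    time with the dipole-convolved susceptibility field (ppb -> dimensionless
    via the single 1e-9 factor applied here).
    """
    consts = consts or PhysioConstants()
    if params.grid_shape != tuple(acq.grid_shape):
        raise ValueError("parameter grid does not match acquisition grid_shape")
    mags = f_qbold(params, acq, consts, G=G)
    chi = chi_qsm(params.Y, params.v, params.chi_n, consts)
    chi = np.where(params.mask, chi, 0.0)
    D = dipole_kernel(params.grid_shape, acq.voxel_size, acq.B0_dir)
    field_ppb = field_from_chi(chi, D)
    w0 = acq.omega0(consts)
    te = np.asarray(acq.echo_times, dtype=float)
    phase = w0 * te[:, None, None, None] * field_ppb[None] * PPB
    return ComplexSignalStack(mags * np.exp(1j * phase), acq)


def oef_from_Y(Y, Ya: float = 0.98):
    """Oxygen extraction fraction OEF = 1 - Y/Ya."""
    if Ya == 0:
        raise ValueError("Ya must be non-zero")
    return 1.0 - np.asarray(Y, dtype=float) / Ya
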