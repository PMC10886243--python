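"""Dual-U-Net parameter estimator and its training losses.

Two encoder–decoder sub-networks — one fed the per-echo signal magnitudes,
one the per-echo tissue phases — each emit parameter maps; the three outputs
common to both branches (Y, v, chi_n) are merged by a learnable per-channel
linear combination and every channel is squashed into its physical bounds
with a tanh.  Training minimizes

    E = E_L1 + 0.1 * E_Model + 0.1 * E_Grad

where E_L1 is the mean absolute difference of z-scored parameter maps,
E_Grad the mean absolute difference of the spatial forward-difference
gradient of the normalized Y map, and E_Model the mean absolute complex
signal difference through the full forward model (or, for the
magnitude+QSM baseline flavour, a magnitude-model term plus a
susceptibility-model term without the dipole convolution).

Everything runs on the hand-rolled float64 layers of :mod:`mcqq._layers`,
so training is deterministic given the seed and intended for desk-scale
smoke configurations (small patches, tens of epochs), not for reproducing
full-scale trained networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._layers import Adam, Conv3d, Deconv3d, Layer, MaxPool3d, ReLU
from .biophysics import (
    PPB,
    AcquisitionParams,
    ComplexSignalStack,
    ParameterMaps,
    PhysioConstants,
    chi_qsm,
    dipole_kernel,
    fs,
    fs_prime,
)
from .inversion import DEFAULT_BOUNDS
from .phantom import NoiseSpec, add_complex_noise

__all__ = [
    "NormStats",
    "NetworkConfig",
    "LossWeights",
    "TrainConfig",
    "DualUNet",
    "z_normalize",
    "z_denormalize",
    "loss_l1",
    "loss_grad",
    "loss_model_mcqq",
    "loss_model_qq",
    "total_loss",
    "build_network",
    "prepare_inputs",
    "train",
    "predict_sliding",
]

PARAMS = ParameterMaps.PARAM_NAMES


# ---------------------------------------------------------------------------
# normalization


@dataclass
class NormStats:
    """Frozen per-parameter z-scoring statistics (order S0, R2, Y, v, chi_n)."""

    mean: np.ndarray
    std: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(5)
        self.std = np.asarray(self.std, dtype=float).reshape(5)
        if np.any(self.std <= 0) or not np.all(np.isfinite(self.std)):
            raise ValueError("std must be positive and finite")

    @classmethod
    def from_maps(cls, maps_list) -> "NormStats":
        """Pooled masked mean/SD over a list of ParameterMaps."""
        cols = [m.stack()[:, m.mask] for m in maps_list]
        allv = np.concatenate(cols, axis=1)
        return cls(mean=allv.mean(axis=1), std=allv.std(axis=1))


def z_normalize(params: ParameterMaps, stats: NormStats) -> np.ndarray:
    """Per-parameter z-score (x - mu) / sigma, shape (5, x, y, z)."""
    arr = params.stack()
    return (arr - stats.mean[:, None, None, None]) / stats.std[:, None, None, None]


def z_denormalize(z: np.ndarray, stats: NormStats) -> np.ndarray:
    """Inverse of :func:`z_normalize` on a (5, x, y, z) stack."""
    z = np.asarray(z, dtype=float)
    return z * stats.std[:, None, None, None] + stats.mean[:, None, None, None]


# ---------------------------------------------------------------------------
# losses (each has a value form and an internal value+gradient form)


@dataclass
class LossWeights:
    """Weights of the composite training loss E = E_L1 + w_model*E_Model + w_grad*E_Grad."""

    w_model: float = 0.1
    w_grad: float = 0.1

    def __post_init__(self) -> None:
        if self.w_model < 0 or self.w_grad < 0:
            raise ValueError("loss weights must be non-negative")


def _masked_count(mask: np.ndarray) -> int:
    n = int(np.count_nonzero(mask))
    if n == 0:
        raise ValueError("empty mask")
    return n


def _loss_l1_grad(z_truth, z_out, mask):
    if z_truth.shape != z_out.shape:
        raise ValueError("shape mismatch between truth and output stacks")
    n = _masked_count(mask)
    d = (z_out - z_truth)[:, mask]
    loss = float(np.abs(d).mean())
    g = np.zeros_like(z_out)
    g[:, mask] = np.sign(d) / (z_out.shape[0] * n)
    return loss, g


def loss_l1(z_truth: np.ndarray, z_out: np.ndarray, mask: np.ndarray) -> float:
    """Mean absolute difference of normalized stacks over masked voxels."""
    return _loss_l1_grad(np.asarray(z_truth, float), np.asarray(z_out, float),
                         np.asarray(mask, bool))[0]


def _fwd_diff(x: np.ndarray, axis: int) -> np.ndarray:
    """Forward difference x[i+1]-x[i] with replicate boundary (last slice 0)."""
    d = np.zeros_like(x)
    sl_lo = [slice(None)] * x.ndim
    sl_hi = [slice(None)] * x.ndim
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    d[tuple(sl_lo)] = x[tuple(sl_hi)] - x[tuple(sl_lo)]
    return d


def _fwd_diff_adjoint(w: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint of :func:`_fwd_diff`: (D^T w)[i] = w[i-1] - w[i] (w[-1]=0)."""
    g = np.zeros_like(w)
    sl_lo = [slice(None)] * w.ndim
    sl_hi = [slice(None)] * w.ndim
    sl_lo[axis] = slice(0, -1)
    sl_hi[axis] = slice(1, None)
    g[tuple(sl_hi)] += w[tuple(sl_lo)]
    g[tuple(sl_lo)] -= w[tuple(sl_lo)]
    return g


def _loss_grad_grad(zy_truth, zy_out, mask):
    if zy_truth.shape != zy_out.shape:
        raise ValueError("shape mismatch between truth and output Y maps")
    n = _masked_count(mask)
    loss = 0.0
    g = np.zeros_like(zy_out)
    for ax in range(zy_out.ndim):
        t = _fwd_diff(zy_out, ax) - _fwd_diff(zy_truth, ax)
        loss += float(np.abs(t[mask]).sum()) / n
        w = np.where(mask, np.sign(t), 0.0) / n
        g += _fwd_diff_adjoint(w, ax)
    return loss, g


def loss_grad(zy_truth: np.ndarray, zy_out: np.ndarray, mask: np.ndarray) -> float:
    """L1 difference of the spatial forward-difference gradients of Y.

    Forward differences along each axis with replicate boundary, absolute
    differences summed over the three axes and averaged over masked voxels.
    Constant offsets between the two maps contribute nothing.
    """
    return _loss_grad_grad(np.asarray(zy_truth, float), np.asarray(zy_out, float),
                           np.asarray(mask, bool))[0]


def _forward_signal_parts(theta, mask, acq, consts, kernel):
    """Magnitude/phase pieces of the forward signal on a (5, x, y, z) stack.

    Returns (S (J,grid) complex, A (J,grid), fs_vals (J,grid), dw (grid),
    chi (grid, masked)).
    """
    S0, R2, Y, v, chi_n = theta
    te = np.asarray(acq.echo_times, dtype=float)
    c1 = (1.0 / 3.0) * consts.gamma * acq.B0 * PPB
    pd = consts.psi_Hb * consts.dchi_Hb
    dw = c1 * (pd * (1.0 - Y) + consts.chi_ba - chi_n)
    x = dw[None] * te[:, None, None, None]
    fs_vals = fs(x)
    A = S0[None] * np.exp(-R2[None] * te[:, None, None, None] - v[None] * fs_vals)
    chi = np.where(mask, chi_qsm(Y, v, chi_n, consts), 0.0)
    fld = np.real(np.fft.ifftn(kernel * np.fft.fftn(chi)))
    w0 = acq.omega0(consts)
    phase = w0 * te[:, None, None, None] * fld[None] * PPB
    S = A * np.exp(1j * phase)
    return S, A, fs_vals, dw, chi


def _model_loss_mcqq_grad(theta_out, theta_truth, mask, acq, consts, kernel):
    """(loss, grad wrt theta_out) of the complex-signal model-consistency loss."""
    te = np.asarray(acq.echo_times, dtype=float)
    J = len(te)
    n = _masked_count(mask)
    S_t, _, _, _, _ = _forward_signal_parts(theta_truth, mask, acq, consts, kernel)
    S_o, A, fs_vals, dw, _ = _forward_signal_parts(theta_out, mask, acq, consts, kernel)
    r = np.where(mask[None], S_o - S_t, 0.0)
    ar = np.abs(r)
    loss = float(ar[:, mask].sum()) / (J * n)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = np.where(ar > 0, r / np.where(ar == 0, 1.0, ar), 0.0)
    # d|S_o - S_t| = Re(conj(u) dS_o); dS_o = e^{i phi} dA + i S_o dphi
    with np.errstate(invalid="ignore"):
        phase_fac = np.where(A > 0, S_o / np.where(A == 0, 1.0, A), 1.0)
    gA = np.real(np.conj(u) * phase_fac) / (J * n)          # dL/dA per echo
    gphi = np.real(np.conj(u) * 1j * S_o) / (J * n)         # dL/dphi per echo
    S0, R2, Y, v, chi_n = theta_out
    tcol = te[:, None, None, None]
    c1 = (1.0 / 3.0) * consts.gamma * acq.B0 * PPB
    pd = consts.psi_Hb * consts.dchi_Hb
    fsd = fs_prime(dw[None] * tcol)
    env = np.where(S0[None] > 0, A / np.where(S0[None] == 0, 1.0, S0[None]),
                   np.exp(-R2[None] * tcol - v[None] * fs_vals))
    g = np.zeros_like(np.asarray(theta_out, dtype=float))
    g[0] = (gA * env).sum(axis=0)
    g[1] = (gA * (-tcol) * A).sum(axis=0)
    g[3] = (gA * (-fs_vals) * A).sum(axis=0)
    # Y and chi_n act on the magnitude through delta-omega
    dA_ddw = gA * (-v[None]) * tcol * fsd * A
    g[2] = (dA_ddw * (-c1 * pd)).sum(axis=0)
    g[4] = (dA_ddw * (-c1)).sum(axis=0)
    # phase pathway: phi_j = w0 t_j 1e-9 (d * chi); dipole kernel self-adjoint
    w0 = acq.omega0(consts)
    wsum = (gphi * (w0 * tcol * PPB)).sum(axis=0)
    gchi = np.real(np.fft.ifftn(kernel * np.fft.fftn(wsum)))
    gchi = np.where(mask, gchi, 0.0)
    a = consts.alpha
    blood = (consts.chi_ba / a
             + pd * (1.0 - Y - (1.0 - a) * consts.Ya) / a)
    g[2] += gchi * (-pd * v / a)
    g[3] += gchi * (blood - chi_n / a)
    g[4] += gchi * (1.0 - v / a)
    g[:, ~mask] = 0.0
    return loss, g


def loss_model_mcqq(params_truth: ParameterMaps, params_out: ParameterMaps,
                    acq: AcquisitionParams,
                    consts: PhysioConstants | None = None) -> float:
    """Model-consistency loss: mean |S(out) - S(truth)| over echoes and mask.

    Both parameter sets are pushed through the full complex forward model
    (qBOLD magnitude times the dipole-convolved susceptibility phase) on the
    acquisition grid; the complex difference modulus is averaged over echoes
    and masked voxels.
    """
    consts = consts or PhysioConstants()
    mask = params_truth.mask
    kernel = dipole_kernel(params_truth.grid_shape, acq.voxel_size, acq.B0_dir)
    loss, _ = _model_loss_mcqq_grad(params_out.stack(), params_truth.stack(),
                                    mask, acq, consts, kernel)
    return loss


def _model_loss_qq_grad(theta_out, theta_truth, mask, acq, consts):
    """(loss, grad) of the decoupled magnitude-model + chi-model loss."""
    te = np.asarray(acq.echo_times, dtype=float)
    J = len(te)
    n = _masked_count(mask)
    tcol = te[:, None, None, None]
    c1 = (1.0 / 3.0) * consts.gamma * acq.B0 * PPB
    pd = consts.psi_Hb * consts.dchi_Hb

    def mag_parts(theta):
        S0, R2, Y, v, chi_n = theta
        dw = c1 * (pd * (1.0 - Y) + consts.chi_ba - chi_n)
        fs_vals = fs(dw[None] * tcol)
        A = S0[None] * np.exp(-R2[None] * tcol - v[None] * fs_vals)
        return A, fs_vals, dw

    A_t, _, _ = mag_parts(theta_truth)
    A_o, fs_vals, dw = mag_parts(theta_out)
    dmag = np.where(mask[None], A_o - A_t, 0.0)
    loss_mag = float(np.abs(dmag[:, mask]).sum()) / (J * n)
    smag = np.sign(dmag) / (J * n)

    S0, R2, Y, v, chi_n = theta_out
    fsd = fs_prime(dw[None] * tcol)
    env = np.where(S0[None] > 0, A_o / np.where(S0[None] == 0, 1.0, S0[None]),
                   np.exp(-R2[None] * tcol - v[None] * fs_vals))
    g = np.zeros_like(np.asarray(theta_out, dtype=float))
    g[0] = (smag * env).sum(axis=0)
    g[1] = (smag * (-tcol) * A_o).sum(axis=0)
    g[3] = (smag * (-fs_vals) * A_o).sum(axis=0)
    dA_ddw = smag * (-v[None]) * tcol * fsd * A_o
    g[2] = (dA_ddw * (-c1 * pd)).sum(axis=0)
    g[4] = (dA_ddw * (-c1)).sum(axis=0)

    chi_t = chi_qsm(theta_truth[2], theta_truth[3], theta_truth[4], consts)
    chi_o = chi_qsm(Y, v, chi_n, consts)
    dchi = np.where(mask, chi_o - chi_t, 0.0)
    loss_chi = float(np.abs(dchi[mask]).sum()) / n
    schi = np.sign(dchi) / n
    a = consts.alpha
    blood = (consts.chi_ba / a
             + pd * (1.0 - Y - (1.0 - a) * consts.Ya) / a)
    g[2] += schi * (-pd * v / a)
    g[3] += schi * (blood - chi_n / a)
    g[4] += schi * (1.0 - v / a)
    g[:, ~mask] = 0.0
    return loss_mag + loss_chi, g


def loss_model_qq(params_truth: ParameterMaps, params_out: ParameterMaps,
                  acq: AcquisitionParams,
                  consts: PhysioConstants | None = None) -> float:
    """Baseline model loss: magnitude-model L1 plus chi-model L1, no convolution."""
    consts = consts or PhysioConstants()
    loss, _ = _model_loss_qq_grad(params_out.stack(), params_truth.stack(),
                                  params_truth.mask, acq, consts)
    return loss


def total_loss(e_l1: float, e_model: float, e_grad: float,
               weights: LossWeights | None = None) -> float:
    """Composite training loss E = E_L1 + w_model*E_Model + w_grad*E_Grad."""
    w = weights or LossWeights()
    if e_l1 < 0 or e_model < 0 or e_grad < 0:
        raise ValueError("loss terms must be non-negative")
    return float(e_l1 + w.w_model * e_model + w.w_grad * e_grad)


# ---------------------------------------------------------------------------
# network


@dataclass
class NetworkConfig:
    """Architecture of the dual U-Net.

    ``depth`` pooling levels with two 3x3x3 convolutions per level on both
    the contracting and expanding paths plus two at the bottleneck, standard
    channel doubling from ``base_channels``, 2x2x2 max pooling and transposed
    convolutions, skip concatenations, and a final 1x1x1 convolution.  At
    the reference settings (depth 4) each sub-network therefore contains
    exactly 18 conv 3x3x3 + 4 pool + 4 deconv + 4 concat + 1 conv 1x1x1.
    """

    depth: int = 4
    base_channels: int = 8
    conv_kernel: int = 3
    pool_kernel: int = 2
    final_kernel: int = 1
    in_channels: int = 8
    out_channels_magnitude: int = 5
    out_channels_phase: int = 3
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.conv_kernel != 3 or self.pool_kernel != 2 or self.final_kernel != 1:
            raise ValueError("supported kernels are conv 3, pool/deconv 2, final 1")
        if self.base_channels < 1 or self.in_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.out_channels_magnitude != 5 or self.out_channels_phase != 3:
            raise ValueError("magnitude branch emits 5 channels, phase branch 3")
        for name in PARAMS:
            lo, hi = self.bounds[name]
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lo < hi")

    def expected_layer_counts(self) -> dict:
        """Per-sub-network layer counts implied by the architecture."""
        d = self.depth
        return {"conv3": 4 * d + 2, "pool": d, "deconv": d, "concat": d, "conv1": 1}


class _Concat(Layer):
    """Channel concatenation of (skip, upsampled); parameter-free."""

    def forward2(self, skip, up):
        self._c_skip = skip.shape[0]
        return np.concatenate([skip, up], axis=0)

    def backward2(self, gy):
        return gy[: self._c_skip], gy[self._c_skip:]


class _Merge(Layer):
    """Learnable per-channel linear combination of the shared (Y, v, chi_n)."""

    def __init__(self):
        super().__init__()
        self.params = {"w_mag": np.full(3, 0.5), "w_phase": np.full(3, 0.5)}
        self.zero_grad()

    def forward2(self, u_mag, u_phase):
        # u_mag: (5, grid) pre-squash; u_phase: (3, grid) for (Y, v, chi_n)
        self._u_mag, self._u_phase = u_mag, u_phase
        out = u_mag.copy()
        wm = self.params["w_mag"][:, None, None, None]
        wp = self.params["w_phase"][:, None, None, None]
        out[2:] = wm * u_mag[2:] + wp * u_phase
        return out

    def backward2(self, gy):
        wm = self.params["w_mag"][:, None, None, None]
        wp = self.params["w_phase"][:, None, None, None]
        self.grads["w_mag"] += (gy[2:] * self._u_mag[2:]).sum(axis=(1, 2, 3))
        self.grads["w_phase"] += (gy[2:] * self._u_phase).sum(axis=(1, 2, 3))
        g_mag = gy.copy()
        g_mag[2:] = gy[2:] * wm
        g_phase = gy[2:] * wp
        return g_mag, g_phase


class _UNet:
    """Single encoder-decoder sub-network (channels, x, y, z) -> (c_out, ...)."""

    def __init__(self, c_in, c_out, depth, base, rng):
        self.depth = depth
        self.enc, self.pools, self.deconvs, self.dec, self.concats = [], [], [], [], []
        c_prev = c_in
        for lvl in range(depth):
            c = base * 2 ** lvl
            self.enc.append([Conv3d(c_prev, c, 3, rng), ReLU(),
                             Conv3d(c, c, 3, rng), ReLU()])
            self.pools.append(MaxPool3d())
            c_prev = c
        c_mid = base * 2 ** depth
        self.mid = [Conv3d(c_prev, c_mid, 3, rng), ReLU(),
                    Conv3d(c_mid, c_mid, 3, rng), ReLU()]
        for lvl in range(depth - 1, -1, -1):
            c = base * 2 ** lvl
            self.deconvs.append(Deconv3d(2 * c, c, rng))
            self.concats.append(_Concat())
            self.dec.append([Conv3d(2 * c, c, 3, rng), ReLU(),
                             Conv3d(c, c, 3, rng), ReLU()])
        self.final = Conv3d(base, c_out, 1, rng)

    def layers(self):
        out = []
        for blk in self.enc:
            out.extend(blk)
        out.extend(self.pools)
        out.extend(self.mid)
        for dcv, cat, blk in zip(self.deconvs, self.concats, self.dec):
            out.append(dcv)
            out.append(cat)
            out.extend(blk)
        out.append(self.final)
        return out

    def layer_counts(self) -> dict:
        counts = {"conv3": 0, "pool": 0, "deconv": 0, "concat": 0, "conv1": 0}
        for ly in self.layers():
            if isinstance(ly, Conv3d):
                counts["conv3" if ly.k == 3 else "conv1"] += 1
            elif isinstance(ly, MaxPool3d):
                counts["pool"] += 1
            elif isinstance(ly, Deconv3d):
                counts["deconv"] += 1
            elif isinstance(ly, _Concat):
                counts["concat"] += 1
        return counts

    def forward(self, x):
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            for ly in blk:
                x = ly.forward(x)
            skips.append(x)
            x = pool.forward(x)
        for ly in self.mid:
            x = ly.forward(x)
        for dcv, cat, blk, skip in zip(self.deconvs, self.concats, self.dec,
                                       reversed(skips)):
            x = dcv.forward(x)
            x = cat.forward2(skip, x)
            for ly in blk:
                x = ly.forward(x)
        return self.final.forward(x)

    def backward(self, gy):
        g = self.final.backward(gy)
        g_skips = [None] * self.depth
        for i in range(self.depth - 1, -1, -1):
            for ly in reversed(self.dec[i]):
                g = ly.backward(g)
            gs, g = self.concats[i].backward2(g)
            g_skips[self.depth - 1 - i] = gs
            g = self.deconvs[i].backward(g)
        for ly in reversed(self.mid):
            g = ly.backward(g)
        for lvl in range(self.depth - 1, -1, -1):
            g = self.pools[lvl].backward(g)
            g = g + g_skips[lvl]
            for ly in reversed(self.enc[lvl]):
                g = ly.backward(g)
        return g


class DualUNet:
    """Magnitude + phase dual U-Net with linear merge and tanh bounding."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.mag_net = _UNet(cfg.in_channels, cfg.out_channels_magnitude,
                             cfg.depth, cfg.base_channels, rng)
        self.phase_net = _UNet(cfg.in_channels, cfg.out_channels_phase,
                               cfg.depth, cfg.base_channels, rng)
        self.merge = _Merge()
        self.lo = np.array([cfg.bounds[n][0] for n in PARAMS])
        self.hi = np.array([cfg.bounds[n][1] for n in PARAMS])

    def layers(self):
        return self.mag_net.layers() + self.phase_net.layers() + [self.merge]

    def layer_counts(self) -> dict:
        """Per-sub-network layer counts (identical for both branches)."""
        return self.mag_net.layer_counts()

    def forward(self, x_mag: np.ndarray, x_phase: np.ndarray) -> np.ndarray:
        """(in_channels, x, y, z) inputs -> bounded (5, x, y, z) parameter stack."""
        u_mag = self.mag_net.forward(np.asarray(x_mag, dtype=float))
        u_phase = self.phase_net.forward(np.asarray(x_phase, dtype=float))
        self._pre_mag, self._pre_phase = u_mag, u_phase
        u = self.merge.forward2(u_mag, u_phase)
        self._tanh = np.tanh(u)
        mid = 0.5 * (self.lo + self.hi)[:, None, None, None]
        half = 0.5 * (self.hi - self.lo)[:, None, None, None]
        return mid + half * self._tanh

    def backward(self, g_out: np.ndarray) -> None:
        half = 0.5 * (self.hi - self.lo)[:, None, None, None]
        gu = g_out * half * (1.0 - self._tanh ** 2)
        g_mag, g_phase = self.merge.backward2(gu)
        self.mag_net.backward(g_mag)
        self.phase_net.backward(g_phase)

    def get_state(self) -> dict:
        """Flat name -> array copy of all parameters (checkpointing)."""
        state = {}
        for i, ly in enumerate(self.layers()):
            for k, v in ly.params.items():
                state[f"layer{i:03d}.{k}"] = v.copy()
        return state

    def set_state(self, state: dict) -> None:
        for i, ly in enumerate(self.layers()):
            for k in ly.params:
                ly.params[k][...] = state[f"layer{i:03d}.{k}"]


def build_network(cfg: NetworkConfig | None = None) -> DualUNet:
    """Construct the dual U-Net and verify the layer-count invariant.

    At the reference settings (depth 4) each sub-network must introspect to
    exactly 18 conv 3x3x3, 4 max-pool, 4 transposed-conv, 4 concatenation
    and 1 conv 1x1x1 layers; any mismatch between the constructed network
    and the architecture formula is a construction error.
    """
    cfg = cfg or NetworkConfig()
    model = DualUNet(cfg)
    expected = cfg.expected_layer_counts()
    for net_name, net in (("magnitude", model.mag_net), ("phase", model.phase_net)):
        got = net.layer_counts()
        if got != expected:
            raise RuntimeError(
                f"{net_name} sub-network layer counts {got} violate the "
                f"architecture invariant {expected}")
    return model


# ---------------------------------------------------------------------------
# input preparation, training, prediction


def prepare_inputs(magnitudes: np.ndarray, phases: np.ndarray,
                   mask: np.ndarray) -> tuple:
    """Per-channel z-scoring of network inputs over masked voxels.

    Magnitude channels are the (compensated) echo magnitudes, phase channels
    the per-echo tissue phase in radians.  Channels that are constant inside
    the mask z-score to exactly zero.
    """
    mask = np.asarray(mask, bool)
    _masked_count(mask)
    out = []
    for arr in (np.asarray(magnitudes, float), np.asarray(phases, float)):
        vals = arr[:, mask]
        mu = vals.mean(axis=1)
        sd = vals.std(axis=1)
        sd = np.where(sd < 1e-12, 1.0, sd)
        out.append((arr - mu[:, None, None, None]) / sd[:, None, None, None])
    return out[0], out[1]


@dataclass
class TrainConfig:
    """Desk-scale training configuration.

    Batch size is fixed at 1 patch; patch positions, brain order and noise
    instances are re-drawn from a fresh ``seed + epoch`` stream every epoch.
    ``model_loss`` selects the model-consistency term: ``"mcqq"`` (complex
    signal through the dipole convolution) or ``"qq"`` (magnitude + chi,
    decoupled).
    """

    epochs: int = 20
    lr: float = 1e-4
    snr_db: float = 20.0
    patch_shape: tuple = (32, 32, 16)
    seed: int = 0
    model_loss: str = "mcqq"
    weights: LossWeights = field(default_factory=LossWeights)
    batch_size: int = 1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be non-negative")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")
        if self.model_loss not in ("mcqq", "qq"):
            raise ValueError("model_loss must be 'mcqq' or 'qq'")


def _check_patch_shape(patch_shape, depth, volume_shape=None):
    ps = tuple(int(n) for n in patch_shape)
    m = 2 ** depth
    if any(n % m for n in ps):
        raise ValueError(f"patch dimensions {ps} must be divisible by 2^depth = {m}")
    if volume_shape is not None and any(p > s for p, s in zip(ps, volume_shape)):
        raise ValueError(f"patch {ps} larger than volume {tuple(volume_shape)}")
    return ps


def _patch_corner(rng, volume_shape, ps, mask):
    """Random patch corner whose patch intersects the mask (20 tries, else centered)."""
    hi = [s - p for s, p in zip(volume_shape, ps)]
    for _ in range(20):
        c = tuple(int(rng.integers(0, h + 1)) for h in hi)
        sl = tuple(slice(ci, ci + pi) for ci, pi in zip(c, ps))
        if mask[sl].any():
            return sl
    return tuple(slice(h // 2, h // 2 + p) for h, p in zip(hi, ps))


def _step_losses(model, truth_patch, mask_patch, noisy_patch, stats, acq_patch,
                 consts, kernel, cfg):
    """One forward/backward pass; returns (total, e_l1, e_model, e_grad)."""
    x_mag, x_phase = prepare_inputs(np.abs(noisy_patch), np.angle(noisy_patch),
                                    mask_patch)
    out = model.forward(x_mag, x_phase)
    sd = stats.std[:, None, None, None]
    z_truth = (truth_patch - stats.mean[:, None, None, None]) / sd
    z_out = (out - stats.mean[:, None, None, None]) / sd
    e_l1, g_l1 = _loss_l1_grad(z_truth, z_out, mask_patch)
    e_gr, g_gr_y = _loss_grad_grad(z_truth[2], z_out[2], mask_patch)
    theta_truth = np.where(mask_patch[None], truth_patch, 0.0)
    theta_out = np.where(mask_patch[None], out, 0.0)
    if cfg.model_loss == "mcqq":
        e_mod, g_mod = _model_loss_mcqq_grad(theta_out, theta_truth, mask_patch,
                                             acq_patch, consts, kernel)
    else:
        e_mod, g_mod = _model_loss_qq_grad(theta_out, theta_truth, mask_patch,
                                           acq_patch, consts)
    w = cfg.weights
    total = total_loss(e_l1, e_mod, e_gr, w)
    # chain normalized-space gradients back to physical output units
    g_out = g_l1 / sd + w.w_model * g_mod
    g_out[2] += w.w_grad * g_gr_y / stats.std[2]
    model.backward(g_out)
    return total, e_l1, e_mod, e_gr


def train(model: DualUNet, brains, acq: AcquisitionParams,
          consts: PhysioConstants | None = None,
          cfg: TrainConfig | None = None,
          stats: NormStats | None = None,
          val_brains=None) -> dict:
    """Train on phantom brains with Adam, batch size 1 patch.

    ``brains`` is a sequence of ParameterMaps; the noise-free signal of each
    brain is simulated once, and every epoch draws a fresh noise instance,
    a fresh brain order and fresh patch positions from ``seed + epoch``.
    Divergence (non-finite loss) aborts with a diagnostic.  Returns a dict
    with per-step ``history`` (columns total, e_l1, e_model, e_grad) and
    per-epoch mean ``epoch_loss``.

    If ``val_brains`` is given, a *fixed* validation batch (one centred
    patch per brain, one frozen noise instance) is evaluated before
    training and after every epoch; its normalized-L1 error is returned as
    ``val_l1`` (length epochs+1, entry 0 = untrained network).  Because the
    validation batch never changes, ``val_l1`` is exactly constant when the
    learning rate is zero, whereas the training stream re-samples patches
    and noise each epoch by design.
    """
    from .biophysics import simulate_signal

    consts = consts or PhysioConstants()
    cfg = cfg or TrainConfig()
    if not brains:
        raise ValueError("need at least one training brain")
    ps = _check_patch_shape(cfg.patch_shape, model.cfg.depth,
                            brains[0].grid_shape)
    if stats is None:
        stats = NormStats.from_maps(brains)
    clean = [simulate_signal(b, acq, consts).data for b in brains]
    stacks = [b.stack() for b in brains]
    sigmas = []
    for b, c in zip(brains, clean):
        sigmas.append(float(np.abs(c[0])[b.mask].mean()) * 10.0 ** (-cfg.snr_db / 20.0))
    acq_patch = AcquisitionParams(echo_times=acq.echo_times, B0=acq.B0,
                                  B0_dir=acq.B0_dir, voxel_size=acq.voxel_size,
                                  grid_shape=ps)
    kernel = dipole_kernel(ps, acq.voxel_size, acq.B0_dir)
    val_batch = None
    if val_brains:
        vrng = np.random.default_rng(cfg.seed + 999_983)
        val_batch = []
        for vb in val_brains:
            _check_patch_shape(ps, model.cfg.depth, vb.grid_shape)
            sl = tuple(slice((s - p) // 2, (s - p) // 2 + p)
                       for s, p in zip(vb.grid_shape, ps))
            vclean = simulate_signal(vb, acq, consts).data
            vsig = float(np.abs(vclean[0])[vb.mask].mean()) * 10.0 ** (-cfg.snr_db / 20.0)
            vnoisy = vclean + vsig * (vrng.standard_normal(vclean.shape)
                                      + 1j * vrng.standard_normal(vclean.shape))
            val_batch.append((vb.stack()[(slice(None),) + sl], vb.mask[sl],
                              vnoisy[(slice(None),) + sl]))

    def val_l1():
        errs = []
        for truth_p, mask_p, noisy_p in val_batch:
            x_mag, x_phase = prepare_inputs(np.abs(noisy_p), np.angle(noisy_p), mask_p)
            out = model.forward(x_mag, x_phase)
            sd = stats.std[:, None, None, None]
            mu = stats.mean[:, None, None, None]
            errs.append(loss_l1((truth_p - mu) / sd, (out - mu) / sd, mask_p))
        return float(np.mean(errs))

    opt = Adam(model.layers(), lr=cfg.lr)
    history, epoch_loss = [], []
    val_hist = [val_l1()] if val_batch else None
    for epoch in range(cfg.epochs):
        rng = np.random.default_rng(cfg.seed + epoch)
        order = rng.permutation(len(brains))
        ep = []
        for bi in order:
            noise = (rng.standard_normal(clean[bi].shape)
                     + 1j * rng.standard_normal(clean[bi].shape))
            noisy = clean[bi] + sigmas[bi] * noise
            sl = _patch_corner(rng, brains[bi].grid_shape, ps, brains[bi].mask)
            opt.zero_grad()
            losses = _step_losses(model, stacks[bi][(slice(None),) + sl],
                                  brains[bi].mask[sl], noisy[(slice(None),) + sl],
                                  stats, acq_patch, consts, kernel, cfg)
            if not all(np.isfinite(losses)):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}, brain {bi}: "
                    f"total={losses[0]}, e_l1={losses[1]}, "
                    f"e_model={losses[2]}, e_grad={losses[3]}")
            opt.step()
            history.append(losses)
            ep.append(losses[0])
        epoch_loss.append(float(np.mean(ep)))
        if val_batch:
            val_hist.append(val_l1())
    out = {"history": np.asarray(history), "epoch_loss": np.asarray(epoch_loss),
           "stats": stats}
    if val_batch:
        out["val_l1"] = np.asarray(val_hist)
    return out


def predict_sliding(model: DualUNet, signal: ComplexSignalStack,
                    mask: np.ndarray, patch_shape=(32, 32, 16),
                    overlap: float = 0.3,
                    return_coverage: bool = False):
    """Whole-volume inference by sliding patches with uniform overlap averaging.

    Patches of ``patch_shape`` are placed with stride (1-overlap)*patch along
    each axis (the final patch clamped to the volume edge); overlapping
    predictions are averaged with uniform weights.  A patch larger than the
    volume falls back to a single zero-padded patch.  Inputs are z-scored
    per channel over the whole-volume mask, so a spatially constant input
    volume enters the network as all zeros.
    """
    if not 0.0 <= overlap <= 0.9:
        raise ValueError("overlap must lie in [0, 0.9]")
    mask = np.asarray(mask, bool)
    ps = _check_patch_shape(patch_shape, model.cfg.depth)
    vol = signal.data.shape[1:]
    x_mag, x_phase = prepare_inputs(np.abs(signal.data), np.angle(signal.data), mask)

    if any(p > s for p, s in zip(ps, vol)):
        # single-patch fallback: zero-pad up to the patch size, predict, crop
        pad = [(0, max(p - s, 0)) for p, s in zip(ps, vol)]
        big = tuple(max(p, s) for p, s in zip(ps, vol))
        big = _check_patch_shape(big, model.cfg.depth) if all(
            b % 2 ** model.cfg.depth == 0 for b in big) else tuple(
            -(-b // 2 ** model.cfg.depth) * 2 ** model.cfg.depth for b in big)
        pad = [(0, b - s) for b, s in zip(big, vol)]
        xm = np.pad(x_mag, [(0, 0)] + pad)
        xp = np.pad(x_phase, [(0, 0)] + pad)
        out = model.forward(xm, xp)[:, : vol[0], : vol[1], : vol[2]]
        cov = np.ones(vol)
        arr = out
    else:
        acc = np.zeros((5,) + vol)
        cov = np.zeros(vol)
        corners = []
        for ax in range(3):
            stride = max(int(round(ps[ax] * (1.0 - overlap))), 1)
            cs = list(range(0, vol[ax] - ps[ax] + 1, stride))
            if cs[-1] != vol[ax] - ps[ax]:
                cs.append(vol[ax] - ps[ax])
            corners.append(cs)
        for cx in corners[0]:
            for cy in corners[1]:
                for cz in corners[2]:
                    sl = (slice(cx, cx + ps[0]), slice(cy, cy + ps[1]),
                          slice(cz, cz + ps[2]))
                    out = model.forward(x_mag[(slice(None),) + sl],
                                        x_phase[(slice(None),) + sl])
                    acc[(slice(None),) + sl] += out
                    cov[sl] += 1.0
        arr = acc / cov[None]
    arr = np.where(mask[None], arr, 0.0)
    params = ParameterMaps.from_stack(arr, mask)
    return (params, cov) if return_coverage else params
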