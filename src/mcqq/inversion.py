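"""Maximum-likelihood inversion of the forward signal model.

Three estimators are provided, mirroring the two noise philosophies:

* :func:`fit_mcqq_joint` — joint ML fit of (S0, R2, Y, v, chi_n) over all
  masked voxels under i.i.d. complex Gaussian noise, with the dipole
  convolution inside the objective (the phase couples voxels).
* :func:`fit_mcqq_oracle_field` — per-voxel complex-domain fit with the
  tissue field supplied, optionally constrained by a measured
  susceptibility; decouples the likelihood question from the convolution.
* :func:`fit_qq_baseline` — per-voxel Gaussian least squares on echo
  magnitudes plus a weighted susceptibility residual: the baseline that
  treats magnitude and chi noise as Gaussian.

Bound constraints are enforced by a smooth hyperbolic-tangent
reparameterization (the same device the networks use), so the constrained
problems become unconstrained.

The objective is severely non-convex: the magnitude model carries the
well-known flat valley coupling venous oxygenation, blood volume and the
characteristic frequency, and the dipole kernel's conical zero surface
makes the phase-to-susceptibility direction ill-conditioned.  Plain descent
stalls in spurious minima, so the joint solver is staged:

1. per-voxel variable projection — the log-magnitude model is linear in
   (ln S0, R2, v) once |delta_omega| is fixed, so a global 1-D scan over
   |delta_omega| finds the per-voxel magnitude optimum without local minima;
2. a linear LSMR solve for (Y, chi_n) from the phase-derived field — at
   fixed v the voxel susceptibility is linear in (Y, chi_n); the magnitude's
   |delta_omega| estimate enters as extra rows weighted by its per-voxel
   standard error, and unit-ridge rows centered on the init regularize the
   dipole-cone null space;
3. a Gauss–Newton (trust-region reflective, matrix-free LSMR) polish of the
   full complex objective.

The per-voxel modes use a vectorized Levenberg–Marquardt iteration (batched
5x5 normal equations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, lsmr

from .biophysics import (
    AcquisitionParams,
    ComplexSignalStack,
    ParameterMaps,
    PhysioConstants,
    PPB,
    chi_qsm,
    dipole_kernel,
    field_from_chi,
    fs,
    fs_prime,
    oef_from_Y,
)

__all__ = ["FitConfig", "FitResult", "fit_mcqq_joint", "fit_mcqq_oracle_field",
           "fit_qq_baseline", "DEFAULT_BOUNDS"]

# physiological expectation for Y and v; remaining bounds from the cohort
# parameter ranges
DEFAULT_BOUNDS = {
    "S0": (1.04, 2.12),
    "R2": (7.3, 161.1),
    "Y": (0.0, 1.0),
    "v": (0.005, 0.055),
    "chi_n": (-957.2, 159.7),
}

PARAMS = ParameterMaps.PARAM_NAMES


@dataclass
class FitConfig:
    """Solver configuration.

    ``init`` selects the starting point: ``population_mean`` (cohort mean
    values), ``truth_perturbed`` (``init_maps`` scaled by a uniform +/-
    ``perturb_frac`` relative perturbation — for self-consistency
    experiments) or ``custom`` (``init_maps`` as given).  The non-convex
    objectives are init-sensitive, which is why the choice is explicit.
    """

    mode: str = "mcqq_joint"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    init: str = "population_mean"
    init_maps: ParameterMaps | None = None
    perturb_frac: float = 0.1
    max_iter: int = 500
    gtol: float = 1e-8
    seed: int = 0
    lambda_chi: float = 1.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ValueError(f"bounds for {name}: need lo < hi, got {lo} >= {hi}")


@dataclass
class FitResult:
    params: ParameterMaps
    oef: np.ndarray
    objective: float
    objective_trace: list
    converged: np.ndarray
    n_iter: int


# ---------------------------------------------------------------------------
# tanh bound reparameterization


def _squash(u, lo, hi):
    return lo + (hi - lo) * 0.5 * (np.tanh(u) + 1.0)


def _squash_deriv(u, lo, hi):
    t = np.tanh(u)
    return (hi - lo) * 0.5 * (1.0 - t * t)


def _unsquash(theta, lo, hi):
    frac = np.clip((np.asarray(theta, float) - lo) / (hi - lo), 1e-12, 1 - 1e-12)
    return np.arctanh(2.0 * frac - 1.0)


def _bounds_arrays(bounds):
    lo = np.array([bounds[n][0] for n in PARAMS])[:, None]
    hi = np.array([bounds[n][1] for n in PARAMS])[:, None]
    return lo, hi


def _initial_theta(truth_vox, cfg: FitConfig, lo, hi, rng, n_vox: int) -> np.ndarray:
    """Initial parameter values (5, N) strictly inside the bounds."""
    if cfg.init == "truth_perturbed":
        if truth_vox is None:
            raise ValueError("truth_perturbed init requires cfg.init_maps")
        theta = truth_vox * (1.0 + cfg.perturb_frac * rng.uniform(-1, 1, truth_vox.shape))
    elif cfg.init == "population_mean":
        from .phantom import TISSUE_STATS
        means = np.array([TISSUE_STATS[n][0] for n in PARAMS])[:, None]
        theta = np.broadcast_to(means, (5, n_vox)).copy()
    elif cfg.init == "custom":
        if truth_vox is None:
            raise ValueError("custom init requires cfg.init_maps")
        theta = truth_vox.copy()
    else:
        raise ValueError(f"unknown init {cfg.init!r}")
    return np.clip(theta, lo, hi)


# ---------------------------------------------------------------------------
# model pieces at masked voxels


def _mag_model(theta, te, consts: PhysioConstants, B0):
    """qBOLD magnitudes (J, N) and dict of dM/dparam arrays (J, N)."""
    S0, R2, Y, v, chi_n = theta
    c1 = (1.0 / 3.0) * consts.gamma * B0 * PPB
    dw = c1 * (consts.psi_Hb * consts.dchi_Hb * (1.0 - Y) + consts.chi_ba - chi_n)
    t = te[:, None]
    x = dw[None, :] * t
    fsx = fs(x)
    fspx = fs_prime(x)
    E = np.exp(-R2[None, :] * t - v[None, :] * fsx)
    M = S0[None, :] * E
    ddw_dY = -c1 * consts.psi_Hb * consts.dchi_Hb
    ddw_dchin = -c1
    dM = {
        "S0": E,
        "R2": -t * M,
        "v": -fsx * M,
        "Y": -v[None, :] * t * fspx * ddw_dY * M,
        "chi_n": -v[None, :] * t * fspx * ddw_dchin * M,
    }
    return M, dM


def _chi_model(theta, consts: PhysioConstants):
    """chi_qsm at voxel vectors plus partials (each (N,))."""
    _, _, Y, v, chi_n = theta
    a = consts.alpha
    pd = consts.psi_Hb * consts.dchi_Hb
    blood = consts.chi_ba / a + pd * (1.0 - Y - (1.0 - a) * consts.Ya) / a
    chi = blood * v + (1.0 - v / a) * chi_n
    dchi = {
        "S0": np.zeros_like(Y),
        "R2": np.zeros_like(Y),
        "Y": -pd / a * v,
        "v": blood - chi_n / a,
        "chi_n": 1.0 - v / a,
    }
    return chi, dchi


def _result(theta, mask, grid_shape, objective, trace, converged, n_iter,
            consts) -> FitResult:
    maps = {}
    for i, name in enumerate(PARAMS):
        full = np.zeros(grid_shape)
        full[mask] = theta[i]
        maps[name] = full
    params = ParameterMaps(mask=mask, **maps)
    oef = np.where(mask, oef_from_Y(params.Y, consts.Ya), 0.0)
    return FitResult(params=params, oef=oef, objective=float(objective),
                     objective_trace=list(trace), converged=converged,
                     n_iter=n_iter)


# ---------------------------------------------------------------------------
# batched per-voxel Levenberg-Marquardt


def _batched_lm(build, u0, max_iter=60, gtol=1e-8):
    """Levenberg-Marquardt over independent voxels, vectorized.

    ``build(u)`` returns per-voxel residuals ``r`` (R, N) and u-space
    Jacobian ``Jr`` (R, 5, N).  Damping adapts per voxel; a step is accepted
    only where it lowers that voxel's cost, so the total objective trace is
    non-increasing.
    """
    u = u0.copy()
    r, Jr = build(u)
    cost = np.sum(r * r, axis=0)
    lam = np.full(u.shape[1], 1e-3)
    trace = [float(cost.sum())]
    gnorm = np.full(u.shape[1], np.inf)
    for _ in range(max_iter):
        JTJ = np.einsum("ran,rbn->nab", Jr, Jr)
        g = np.einsum("ran,rn->na", Jr, r)
        gnorm = np.abs(g).max(axis=1)
        diag = np.einsum("naa->na", JTJ)
        A = JTJ + (lam[:, None] * np.maximum(diag, 1e-12))[:, :, None] * np.eye(5)
        try:
            step = np.linalg.solve(A, -g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            A = A + 1e-8 * np.eye(5)
            step = np.linalg.solve(A, -g[..., None])[..., 0]
        u_new = u + step.T
        r_new, Jr_new = build(u_new)
        cost_new = np.sum(r_new * r_new, axis=0)
        accept = cost_new < cost
        u[:, accept] = u_new[:, accept]
        r[:, accept] = r_new[:, accept]
        Jr[:, :, accept] = Jr_new[:, :, accept]
        cost = np.where(accept, cost_new, cost)
        lam = np.where(accept, lam / 3.0, lam * 4.0)
        lam = np.clip(lam, 1e-10, 1e10)
        trace.append(float(cost.sum()))
        if gnorm.max() <= gtol:
            break
    converged = gnorm <= np.maximum(gtol, 1e-6 * (1.0 + cost))
    return u, cost, trace, converged


def _staged_init(mag, te, chi_vox_meas, theta_ref, consts, B0, lo, hi):
    """List of per-voxel staged initial guesses, each (5, N).

    Variable projection over |delta_omega| fits (ln S0, R2, v) to the
    log-magnitudes; the sign of delta_omega comes from the reference
    parameters.  If a measured susceptibility is supplied, (Y, chi_n)
    follow exactly from the delta_omega and chi constraints — chi is affine
    in Y with slope -psi_Hb*dchi_Hb once delta_omega is pinned; otherwise Y
    is kept from the reference and chi_n chosen to match delta_omega.
    """
    c1 = (1.0 / 3.0) * consts.gamma * B0 * PPB
    pd = consts.psi_Hb * consts.dchi_Hb
    a = consts.alpha
    dw_bound = c1 * (pd + abs(consts.chi_ba) + max(abs(lo[4, 0]), abs(hi[4, 0])))
    (lnS0, R2e, ve, dwe), _, _, free = _varpro_magnitude(
        mag, te, lo, hi, dw_max=float(dw_bound))
    dw_ref = c1 * (pd * (1.0 - theta_ref[2]) + consts.chi_ba - theta_ref[4])

    cand = []
    # both the bounded-scan and the raw unconstrained-sweep magnitude
    # solutions seed candidates; the caller picks per voxel by model cost
    for lnS0_s, R2_s, v_s, dwa in ((lnS0, R2e, ve, dwe),
                                   (free[0], free[1], free[2], free[3])):
        # sign of delta_omega is invisible to the magnitude; reference sign
        dw = np.where(dw_ref < 0, -dwa, dwa)
        v_e = np.clip(v_s, lo[3, 0], hi[3, 0])
        if chi_vox_meas is not None:
            # chi(Y) at fixed delta_omega is affine with slope -pd
            def chi_of(Y):
                chin = pd * (1.0 - Y) + consts.chi_ba - dw / c1
                blood = (consts.chi_ba / a
                         + pd * (1.0 - Y - (1.0 - a) * consts.Ya) / a)
                return blood * v_e + (1.0 - v_e / a) * chin

            Y_e = (chi_of(np.zeros_like(v_e)) - chi_vox_meas) / pd
        else:
            Y_e = theta_ref[2].copy()
        Y_e = np.clip(Y_e, lo[2, 0], hi[2, 0])
        chin_e = np.clip(pd * (1.0 - Y_e) + consts.chi_ba - dw / c1,
                         lo[4, 0], hi[4, 0])
        S0_e = np.clip(np.exp(np.minimum(lnS0_s, 50.0)), lo[0, 0], hi[0, 0])
        R2_e = np.clip(R2_s, lo[1, 0], hi[1, 0])
        cand.append(np.vstack([S0_e, R2_e, Y_e, v_e, chin_e]))
        if chi_vox_meas is not None:
            # alternative split for voxels whose |delta_omega| is
            # magnitude-blind (small v): trust chi for chi_n and keep Y
            # from the reference
            Y_b = np.clip(theta_ref[2], lo[2, 0], hi[2, 0])
            blood_b = (consts.chi_ba / a
                       + pd * (1.0 - Y_b - (1.0 - a) * consts.Ya) / a)
            chin_b = np.clip((chi_vox_meas - blood_b * v_e) / (1.0 - v_e / a),
                             lo[4, 0], hi[4, 0])
            cand.append(np.vstack([S0_e, R2_e, Y_b, v_e, chin_b]))
    return cand


def _best_start(build, lo, hi, candidates):
    """u-space start from the per-voxel lowest-cost candidate theta.

    Starting u values are clamped to [-3, 3]: a candidate clipped to a hard
    bound would otherwise start where the tanh derivative vanishes and the
    parameter could never move again.
    """
    us, costs = [], []
    for theta in candidates:
        u = np.clip(_unsquash(theta, lo, hi), -3.0, 3.0)
        r, _ = build(u)
        us.append(u)
        costs.append(np.sum(r * r, axis=0))
    pick = np.argmin(np.stack(costs), axis=0)
    u0 = us[0].copy()
    for i in range(1, len(us)):
        sel = pick == i
        u0[:, sel] = us[i][:, sel]
    return u0


# ---------------------------------------------------------------------------
# staged joint solver


def _varpro_magnitude(mag, te, lo, hi, dw_max=600.0, n_grid=300, n_v=24):
    """Per-voxel global magnitude fit via bounded variable projection.

    Scans a (|delta_omega|, v) grid; at each grid point the log-magnitude
    model is a straight line in echo time, z = ln S0 - R2*t with
    z = ln(mag) + v*fs(|dw|*t), solved in closed form per voxel with
    magnitude-squared weights (so the fit approximates linear-domain least
    squares and late low-signal echoes are de-emphasized).  v must be
    scanned rather than solved linearly: for large |dw| the fs term is
    collinear with the line basis, and an unconstrained linear solve would
    admit degenerate large-|dw| solutions with unphysical v.  Returns a
    (4, N) array of per-voxel (ln S0, R2, v, |delta_omega|), then a per-voxel
    standard error of |delta_omega| estimated from the curvature of the
    profile residual (v and the line profiled out), so downstream stages can
    down-weight magnitude-blind voxels instead of trusting a noise-driven
    |delta_omega|, and a per-voxel noise-variance estimate (the achieved
    residual per degree of freedom; the magnitude-squared weights make each
    echo's residual term an estimate of the per-channel noise variance), and
    the raw unconstrained-sweep solution (useful as an extra start
    candidate for per-voxel refinement).
    """
    mag = np.maximum(mag, 1e-6)
    y = np.log(mag)
    w = mag * mag  # (J, N) weights
    t = np.asarray(te, float)[:, None]
    S = w.sum(axis=0)
    St = (w * t).sum(axis=0)
    Stt = (w * t * t).sum(axis=0)
    Sy = (w * y).sum(axis=0)
    Sty = (w * t * y).sum(axis=0)
    Syy = (w * y * y).sum(axis=0)
    det = S * Stt - St * St
    v_grid = np.linspace(lo[3, 0], hi[3, 0], n_v)[:, None]  # (V, 1)
    N = y.shape[1]
    best_res = np.full(N, np.inf)
    best = np.zeros((4, N))

    def line_fit(f, v_cand):
        """Weighted line fit of z = y + v*fs; f (J, N) or (J, 1), v (V, N)."""
        Sf = (w * f).sum(axis=0)
        Stf = (w * t * f).sum(axis=0)
        Sff = (w * f * f).sum(axis=0)
        Syf = (w * y * f).sum(axis=0)
        Sz = Sy + v_cand * Sf          # (V, N)
        Stz = Sty + v_cand * Stf
        Szz = Syy + 2.0 * v_cand * Syf + v_cand ** 2 * Sff
        a = (Stt * Sz - St * Stz) / det
        b = (S * Stz - St * Sz) / det
        return a, b, Szz - a * Sz - b * Stz

    def keep_best(a, b, res, v_cand, g_vals):
        iv = np.argmin(res, axis=0)
        rn = np.take_along_axis(res, iv[None, :], axis=0)[0]
        upd = rn < best_res
        if np.any(upd):
            best_res[upd] = rn[upd]
            best[0, upd] = np.take_along_axis(a, iv[None, :], axis=0)[0][upd]
            best[1, upd] = -np.take_along_axis(b, iv[None, :], axis=0)[0][upd]
            best[2, upd] = np.broadcast_to(v_cand, res.shape)[iv, np.arange(N)][upd]
            best[3, upd] = np.broadcast_to(g_vals, (N,))[upd]

    # coarse global scan over (|delta_omega|, v)
    n_fine = n_grid // 2
    grid = np.concatenate([np.linspace(0.0, 60.0, n_fine),
                           np.linspace(60.0 + 1e-3, dw_max, n_grid - n_fine)])
    for g in grid:
        a, b, res = line_fit(fs(g * t), v_grid)
        keep_best(a, b, res, v_grid, g)

    # local per-voxel refinement: the (|dw|, v) residual ridge is nearly
    # flat, so the coarse optimum must be polished before it is usable
    fine_dg = 60.0 / (n_fine - 1)
    coarse_dg = (dw_max - 60.0) / max(n_grid - n_fine - 1, 1)
    step_g = np.where(best[3] <= 60.0, fine_dg, coarse_dg)
    step_v = (hi[3, 0] - lo[3, 0]) / (n_v - 1)
    offs = np.linspace(-1.0, 1.0, 7)
    for _ in range(4):
        for og in offs:
            g_vals = np.clip(best[3] + og * step_g, 0.0, dw_max)
            f = fs(g_vals[None, :] * t)  # (J, N)
            v_cand = np.clip(best[2][None, :] + offs[:, None] * step_v,
                             lo[3, 0], hi[3, 0])
            a, b, res = line_fit(f, v_cand)
            keep_best(a, b, res, v_cand, g_vals)
        step_g *= 0.3
        step_v *= 0.3

    # unconstrained sweep: with v solved linearly the scan is exact in the
    # noiseless limit; only accepted where its v is physical, because with
    # noise the degenerate large-|dw| ridge yields unphysical v
    free_res = np.full(N, np.inf)
    free = np.zeros((4, N))
    tcol = t[:, 0]
    for g in grid:
        B = np.column_stack([np.ones_like(tcol), -tcol, -fs(g * tcol)])
        coef, *_ = np.linalg.lstsq(B, y, rcond=None)
        rn = np.sum((B @ coef - y) ** 2, axis=0)
        upd = rn < free_res
        if np.any(upd):
            free_res[upd] = rn[upd]
            free[:3, upd] = coef[:, upd]
            free[3, upd] = g
    # accept the unconstrained solution only on decisive evidence (residual
    # at least 5x smaller than the bounded scan's): noiseless data passes,
    # while with noise the degenerate ridge offers only marginal gains and
    # the bounded solution is kept; consumers clip v to their own bounds
    a_f, b_f, res_f = line_fit(fs(free[3][None, :] * t), free[2][None, :])
    v_rng = hi[3, 0] - lo[3, 0]
    ok = ((5.0 * res_f[0] < best_res)
          & (free[2] > lo[3, 0] - 0.5 * v_rng)
          & (free[2] < hi[3, 0] + 0.5 * v_rng))
    best[0, ok] = a_f[0, ok]
    best[1, ok] = -b_f[0, ok]
    best[2, ok] = free[2, ok]
    best[3, ok] = free[3, ok]
    best_res[ok] = res_f[0, ok]

    # |delta_omega| standard error: Var(g) ~ 2 sigma^2 / (d^2 res / dg^2)
    # with the residual profiled over v and the linear parameters.  The
    # magnitude-squared weights make each echo's residual term ~ sigma^2, so
    # sigma^2 is estimated from the achieved residual and the echo count.
    J = len(tcol)
    sig2 = np.maximum(best_res, 0.0) / max(J - 4, 1)
    h = np.maximum(1.0, 0.01 * best[3])
    g0 = best[3]
    gm = np.where(g0 >= h, g0 - h, g0 + 2.0 * h)
    gp = g0 + h
    prof = []
    for g_vals in (gm, g0, gp):
        _, _, res = line_fit(fs(g_vals[None, :] * t), v_grid)
        prof.append(res.min(axis=0))
    # second derivative of the quadratic through the three (unequally
    # spaced near the boundary) profile points
    curv = 2.0 * (prof[0] / ((gm - g0) * (gm - gp))
                  + prof[1] / ((g0 - gm) * (g0 - gp))
                  + prof[2] / ((gp - gm) * (gp - g0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_dw = np.sqrt(2.0 * sig2 / curv)
    sigma_dw = np.where(curv > 0, sigma_dw, np.inf)
    return best, sigma_dw, sig2, free


def _field_from_phase(phases, cj):
    """Weighted LS estimate of the per-voxel field (ppb) from echo phases."""
    return np.einsum("j,jn->n", cj, phases) / np.sum(cj * cj)


def fit_mcqq_joint(measured: ComplexSignalStack, acq: AcquisitionParams,
                   consts: PhysioConstants | None = None,
                   cfg: FitConfig | None = None,
                   mask: np.ndarray | None = None) -> FitResult:
    """Joint ML fit under complex Gaussian noise, convolution inside.

    Minimizes sum_j sum_vox |S_meas - S_model(theta)|^2 over masked voxels;
    the susceptibility of every masked voxel feeds the dipole-convolved
    field, so phase residuals couple voxels.  Solved by the staged
    (variable-projection -> linear field solve -> Gauss-Newton) scheme
    described in the module docstring.  If the configured initial point
    already attains a negligible objective (<= 1e-18 per voxel) it is
    returned unchanged.
    """
    consts = consts or PhysioConstants()
    cfg = cfg or FitConfig(mode="mcqq_joint")
    if not np.all(np.isfinite(measured.data)):
        raise ValueError("measurement contains non-finite values")
    if mask is None:
        if cfg.init_maps is None:
            raise ValueError("need a mask (or cfg.init_maps carrying one)")
        mask = cfg.init_maps.mask
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    grid_shape = mask.shape
    N = int(mask.sum())
    te = np.asarray(acq.echo_times, float)
    cj = acq.omega0(consts) * te * PPB
    D = dipole_kernel(grid_shape, acq.voxel_size, acq.B0_dir)
    S_meas = measured.data[:, mask]
    lo, hi = _bounds_arrays(cfg.bounds)
    pad = 1e-9 * (hi - lo)
    rng = np.random.default_rng(cfg.seed)
    truth_vox = cfg.init_maps.stack()[:, mask] if cfg.init_maps is not None else None
    theta_init = _initial_theta(truth_vox, cfg, lo, hi, rng, N)

    def objective_parts(theta):
        M, dM = _mag_model(theta, te, consts, acq.B0)
        chi_vox, dchi = _chi_model(theta, consts)
        cf = np.zeros(grid_shape)
        cf[mask] = chi_vox
        fld = field_from_chi(cf, D)[mask]
        expi = np.exp(1j * cj[:, None] * fld[None, :])
        S = M * expi
        r = S - S_meas
        return M, dM, dchi, expi, S, r

    *_, r0 = objective_parts(theta_init)
    obj0 = float(np.sum(r0.real ** 2 + r0.imag ** 2))
    if obj0 <= 1e-18 * N:
        conv = np.ones(N, dtype=bool)
        return _result(theta_init, mask, grid_shape, obj0, [obj0], conv, 0, consts)

    # --- stage 1: per-voxel magnitude variable projection
    c1 = (1.0 / 3.0) * consts.gamma * acq.B0 * PPB
    pd = consts.psi_Hb * consts.dchi_Hb
    dw_bound = c1 * (pd + abs(consts.chi_ba) + max(abs(lo[4, 0]), abs(hi[4, 0])))
    (lnS0, R2e, ve, dwe), sigma_dw, sig2_vox, _ = _varpro_magnitude(
        np.abs(S_meas), te, lo, hi, dw_max=float(dw_bound))
    # sign of delta_omega is invisible to the magnitude; take it from the init
    dw_init = c1 * (pd * (1.0 - theta_init[2]) + consts.chi_ba - theta_init[4])
    dw_signed = np.where(dw_init < 0, -dwe, dwe)

    # --- stage 2: linear update of (Y, chi_n) from the phase-derived field.
    # At fixed v the voxel susceptibility is linear in (Y, chi_n), so the
    # field measurement, the magnitude's |delta_omega| evidence and priors
    # centered on the init combine into one weighted linear least-squares
    # problem.  The |delta_omega| rows are weighted by the inverse of the
    # per-voxel standard error from stage 1: noiseless data pin delta_omega
    # (and hence the chi_n/Y split) exactly, while magnitude-blind noisy
    # voxels fall back on the field and the priors.
    phases = np.angle(S_meas)
    f_meas = _field_from_phase(phases, cj)
    # field noise estimate from the echo-fit residuals; for noiseless data it
    # vanishes and the field rows dominate
    ph_res = phases - cj[:, None] * f_meas[None, :]
    # the floors keep the weighted system well conditioned for LSMR in the
    # noiseless limit; the data rows still outweigh the priors by >>1e3
    sigma_f = max(float(np.sqrt(np.median(np.sum(ph_res ** 2, axis=0))
                                / max(len(te) - 1, 1) / np.sum(cj * cj))),
                  1e-4)
    v_e = np.clip(ve, lo[3, 0] + pad[3, 0], hi[3, 0] - pad[3, 0])
    a_ = consts.alpha

    def conv_mask(vec):
        full = np.zeros(grid_shape)
        full[mask] = vec
        return field_from_chi(full, D)[mask]

    Y_i = theta_init[2]
    chin_i = theta_init[4]
    # column scaling: unknowns are (dY/sY, dchi_n/sn); the unit-weight prior
    # rows are then a ridge with the cohort spreads as prior SDs, pulling
    # unresolvable dipole-cone components toward the init instead of zero
    sY, sn = 0.1, 37.5
    ca = -pd * v_e / a_           # d chi / dY at fixed chi_n
    cb = 1.0 - v_e / a_           # d chi / d chi_n
    wd = 1.0 / np.maximum(sigma_dw, 1e-2)
    rhs_f = (f_meas - conv_mask(chi_qsm(Y_i, v_e, chin_i, consts))) / sigma_f
    dw0 = c1 * (pd * (1.0 - Y_i) + consts.chi_ba - chin_i)
    rhs_d = wd * (dw_signed - dw0)

    def mv2(x):
        u1, u2 = x[:N], x[N:]
        rf = conv_mask(ca * sY * u1 + cb * sn * u2) / sigma_f
        rd = wd * c1 * (-pd * sY * u1 - sn * u2)
        return np.concatenate([rf, rd, u1, u2])

    def rmv2(w):
        wf, wdw, w1, w2 = w[:N], w[N:2 * N], w[2 * N:3 * N], w[3 * N:]
        cw = conv_mask(wf) / sigma_f
        g1 = sY * (ca * cw - c1 * pd * wd * wdw) + w1
        g2 = sn * (cb * cw - c1 * wd * wdw) + w2
        return np.concatenate([g1, g2])

    op = LinearOperator((4 * N, 2 * N), matvec=mv2, rmatvec=rmv2)
    b = np.concatenate([rhs_f, rhs_d, np.zeros(N), np.zeros(N)])
    sol = lsmr(op, b, maxiter=3000, atol=1e-10, btol=1e-10)
    Y_e = np.clip(Y_i + sY * sol[0][:N],
                  lo[2, 0] + pad[2, 0], hi[2, 0] - pad[2, 0])
    chin_e = np.clip(chin_i + sn * sol[0][N:],
                     lo[4, 0] + pad[4, 0], hi[4, 0] - pad[4, 0])
    theta_stage = np.vstack([
        np.clip(np.exp(lnS0), lo[0, 0] + pad[0, 0], hi[0, 0] - pad[0, 0]),
        np.clip(R2e, lo[1, 0] + pad[1, 0], hi[1, 0] - pad[1, 0]),
        Y_e, v_e, chin_e,
    ])

    # --- stage 3: Levenberg-Marquardt polish of the full complex objective.
    # Iteration stops at the discrepancy level 2*J*N*sigma^2 (expected
    # objective at the true parameters): pushing the likelihood below the
    # noise floor only fits noise through the flat magnitude valley and the
    # dipole cone, inflating the parameter error.  Noiseless data have a
    # vanishing floor, so there the polish runs to convergence.
    J = len(te)
    target = max(2.0 * J * N * float(np.median(sig2_vox)), 1e-18 * N)

    def full_objective(theta):
        *_, r = objective_parts(theta)
        return float(np.sum(r.real ** 2 + r.imag ** 2)), r

    obj_stage, _ = full_objective(theta_stage)
    if obj_stage < obj0:
        u = _unsquash(theta_stage, lo, hi)
        obj = obj_stage
        trace = [obj0, obj_stage]
    else:
        u = _unsquash(theta_init, lo, hi)
        obj = obj0
        trace = [obj0]

    def jac_op(u, theta):
        M, dM, dchi, expi, S, r = objective_parts(theta)
        sd = _squash_deriv(u, lo, hi)

        def matvec(v):
            dth = v.reshape(5, -1) * sd
            dMv = sum(dM[n] * dth[i] for i, n in enumerate(PARAMS))
            dchiv = sum(dchi[n] * dth[i] for i, n in enumerate(PARAMS))
            dfield = conv_mask(dchiv)
            dS = dMv * expi + 1j * S * (cj[:, None] * dfield[None, :])
            return np.concatenate([dS.real.ravel(), dS.imag.ravel()])

        def rmatvec(w):
            wc = (w[:J * N] + 1j * w[J * N:]).reshape(J, N)
            a = (np.conj(wc) * expi).real
            b = (np.conj(wc) * 1j * S).real
            gchi = conv_mask(np.sum(cj[:, None] * b, axis=0))
            g = np.empty((5, N))
            for i, n in enumerate(PARAMS):
                g[i] = np.sum(a * dM[n], axis=0) + gchi * dchi[n]
            return (g * sd).ravel()

        return LinearOperator((2 * J * N, 5 * N), matvec=matvec,
                              rmatvec=rmatvec), r

    lam = 1e-3
    n_iter = 0
    stop = "max_iter"
    for _ in range(cfg.max_iter):
        if obj <= target:
            stop = "discrepancy"
            break
        theta = _squash(u, lo, hi)
        op3, r = jac_op(u, theta)
        rflat = np.concatenate([r.real.ravel(), r.imag.ravel()])
        g = op3.rmatvec(rflat)
        if np.max(np.abs(g)) <= cfg.gtol:
            stop = "gradient"
            break
        improved = False
        for _try in range(8):
            step = lsmr(op3, -rflat, damp=np.sqrt(lam) * max(np.sqrt(obj / max(rflat.size, 1)), 1e-12),
                        maxiter=60, atol=1e-10, btol=1e-10)[0]
            u_try = u + step.reshape(5, -1)
            obj_try, _ = full_objective(_squash(u_try, lo, hi))
            if obj_try < obj:
                u, obj = u_try, obj_try
                trace.append(obj)
                lam = max(lam / 3.0, 1e-12)
                improved = True
                break
            lam *= 10.0
        n_iter += 1
        if not improved:
            stop = "no_step"
            break
    else:
        stop = "max_iter"
    if obj <= target:
        stop = "discrepancy"

    theta = _squash(u, lo, hi)
    converged = np.full(N, stop != "max_iter")
    return _result(theta, mask, grid_shape, obj, trace, converged,
                   n_iter, consts)


# ---------------------------------------------------------------------------
# per-voxel fits


def fit_mcqq_oracle_field(measured: ComplexSignalStack, true_field: np.ndarray,
                          acq: AcquisitionParams,
                          consts: PhysioConstants | None = None,
                          cfg: FitConfig | None = None,
                          mask: np.ndarray | None = None,
                          chi_meas: np.ndarray | None = None,
                          sigma: float = 1.0,
                          sigma_chi: float | None = None) -> FitResult:
    """Per-voxel complex-domain fit with the tissue field supplied (ppb).

    The model phase is fixed by ``true_field``; the complex residual is
    weighted by 1/sigma.  If ``chi_meas`` is given, a Gaussian
    susceptibility residual sqrt(lambda_chi) * (chi_qsm(theta) - chi_meas)
    / sigma_chi is appended, which is what breaks the coupling between
    venous oxygenation and blood volume of the magnitude-only model.
    """
    consts = consts or PhysioConstants()
    cfg = cfg or FitConfig(mode="mcqq_oracle_field")
    if not np.all(np.isfinite(measured.data)):
        raise ValueError("measurement contains non-finite values")
    true_field = np.asarray(true_field, float)
    if mask is None:
        mask = np.ones(true_field.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    grid_shape = mask.shape
    N = int(mask.sum())
    te = np.asarray(acq.echo_times, float)
    cj = acq.omega0(consts) * te * PPB
    expi = np.exp(1j * cj[:, None] * true_field[mask][None, :])
    S_meas = measured.data[:, mask]
    use_chi = chi_meas is not None and cfg.lambda_chi > 0
    if use_chi:
        chi_vox_meas = np.asarray(chi_meas, float)[mask]
        if sigma_chi is None or sigma_chi <= 0:
            raise ValueError("chi constraint requires positive sigma_chi")
        w_chi = np.sqrt(cfg.lambda_chi) / sigma_chi
    w_sig = 1.0 / sigma

    lo, hi = _bounds_arrays(cfg.bounds)
    rng = np.random.default_rng(cfg.seed)
    truth_vox = cfg.init_maps.stack()[:, mask] if cfg.init_maps is not None else None
    theta0 = _initial_theta(truth_vox, cfg, lo, hi, rng, N)

    def build(u):
        theta = _squash(u, lo, hi)
        sd = _squash_deriv(u, lo, hi)
        M, dM = _mag_model(theta, te, consts, acq.B0)
        rc = M * expi - S_meas
        r = np.concatenate([w_sig * rc.real, w_sig * rc.imag], axis=0)
        Jr = np.stack(
            [np.concatenate([w_sig * (dM[n] * expi).real,
                             w_sig * (dM[n] * expi).imag], axis=0)
             for n in PARAMS], axis=1)  # (2J, 5, N)
        if use_chi:
            chi_vox, dchi = _chi_model(theta, consts)
            r = np.concatenate([r, w_chi * (chi_vox - chi_vox_meas)[None, :]], axis=0)
            Jc = np.stack([w_chi * dchi[n] for n in PARAMS])[None, :, :]  # (1,5,N)
            Jr = np.concatenate([Jr, Jc], axis=0)
        return r, Jr * sd[None, :, :]

    # early exit at a residual-free configured init (noiseless fixed point)
    r0, _ = build(_unsquash(theta0, lo, hi))
    obj0 = float(np.sum(r0 * r0))
    if obj0 <= 1e-18 * N:
        conv = np.ones(N, dtype=bool)
        return _result(theta0, mask, grid_shape, obj0, [obj0], conv, 0, consts)
    theta_s = _staged_init(np.abs(S_meas), te, chi_vox_meas if use_chi else None,
                           theta0, consts, acq.B0, lo, hi)
    u0 = _best_start(build, lo, hi, [theta0, *theta_s])
    u, cost, trace, converged = _batched_lm(build, u0, max_iter=cfg.max_iter,
                                            gtol=cfg.gtol)
    theta = _squash(u, lo, hi)
    return _result(theta, mask, grid_shape, float(cost.sum()), trace,
                   converged, len(trace) - 1, consts)


def fit_qq_baseline(magnitudes: np.ndarray, chi_measured: np.ndarray,
                    acq: AcquisitionParams,
                    consts: PhysioConstants | None = None,
                    cfg: FitConfig | None = None,
                    mask: np.ndarray | None = None,
                    sigma: float = 1.0,
                    sigma_chi: float = 1.0) -> FitResult:
    """Per-voxel Gaussian least squares on magnitudes plus chi residual.

    Residual blocks are scaled by their nominal noise SDs and the chi block
    additionally by sqrt(cfg.lambda_chi) (default 1).  Setting
    lambda_chi = 0 yields a magnitude-only qBOLD fit.
    """
    consts = consts or PhysioConstants()
    cfg = cfg or FitConfig(mode="qq_baseline")
    magnitudes = np.asarray(magnitudes, float)
    if not np.all(np.isfinite(magnitudes)):
        raise ValueError("measurement contains non-finite values")
    if mask is None:
        mask = np.ones(magnitudes.shape[1:], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    if chi_measured is None and cfg.lambda_chi > 0:
        raise ValueError("qq_baseline with lambda_chi > 0 requires a chi input")
    grid_shape = mask.shape
    N = int(mask.sum())
    te = np.asarray(acq.echo_times, float)
    mag_meas = magnitudes[:, mask]
    use_chi = cfg.lambda_chi > 0
    if use_chi:
        chi_vox_meas = np.asarray(chi_measured, float)[mask]
        w_chi = np.sqrt(cfg.lambda_chi) / sigma_chi
    w_sig = 1.0 / sigma

    lo, hi = _bounds_arrays(cfg.bounds)
    rng = np.random.default_rng(cfg.seed)
    truth_vox = cfg.init_maps.stack()[:, mask] if cfg.init_maps is not None else None
    theta0 = _initial_theta(truth_vox, cfg, lo, hi, rng, N)

    def build(u):
        theta = _squash(u, lo, hi)
        sd = _squash_deriv(u, lo, hi)
        M, dM = _mag_model(theta, te, consts, acq.B0)
        r = w_sig * (M - mag_meas)
        Jr = np.stack([w_sig * dM[n] for n in PARAMS], axis=1)  # (J,5,N)
        if use_chi:
            chi_vox, dchi = _chi_model(theta, consts)
            r = np.concatenate([r, w_chi * (chi_vox - chi_vox_meas)[None, :]], axis=0)
            Jc = np.stack([w_chi * dchi[n] for n in PARAMS])[None, :, :]
            Jr = np.concatenate([Jr, Jc], axis=0)
        return r, Jr * sd[None, :, :]

    r0, _ = build(_unsquash(theta0, lo, hi))
    obj0 = float(np.sum(r0 * r0))
    if obj0 <= 1e-18 * N:
        conv = np.ones(N, dtype=bool)
        return _result(theta0, mask, grid_shape, obj0, [obj0], conv, 0, consts)
    theta_s = _staged_init(np.maximum(mag_meas, 1e-6), te,
                           chi_vox_meas if use_chi else None,
                           theta0, consts, acq.B0, lo, hi)
    u0 = _best_start(build, lo, hi, [theta0, *theta_s])
    u, cost, trace, converged = _batched_lm(build, u0, max_iter=cfg.max_iter,
                                            gtol=cfg.gtol)
    theta = _squash(u, lo, hi)
    return _result(theta, mask, grid_shape, float(cost.sum()), trace,
                   converged, len(trace) - 1, consts)
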