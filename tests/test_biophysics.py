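import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import j0

from mcqq.biophysics import (
    AcquisitionParams,
    ComplexSignalStack,
    ParameterMaps,
    PhysioConstants,
    chi_from_field,
    chi_qsm,
    chi_qsm_mixture,
    delta_omega,
    dipole_kernel,
    f_bold,
    f_qbold,
    field_from_chi,
    fs,
    fs_prime,
    fs_quadrature,
    oef_from_Y,
    simulate_signal,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# constants and delta_omega


def test_printed_constants(consts):
    assert consts.gamma == 267.51e6
    assert consts.psi_Hb == 0.0909
    assert consts.dchi_Hb == 12522.0
    assert consts.chi_ba == -108.3
    assert consts.Hct == 0.357
    assert consts.alpha == 0.77
    assert consts.Ya == 0.98


def test_constants_validation():
    with pytest.raises(ValueError):
        PhysioConstants(alpha=0.0)
    with pytest.raises(ValueError):
        PhysioConstants(Ya=1.5)
    with pytest.raises(ValueError):
        PhysioConstants(psi_Hb=-1.0)


def test_delta_omega_hand_value(consts):
    # (1/3) * 2.6751e8 * 3 * (0.0909*12522*0.02 - 108.3) * 1e-9 ~= -22.88 rad/s
    got = delta_omega(0.98, 0.0, consts, B0=3.0)
    expect = (1.0 / 3.0) * 267.51e6 * 3.0 * (0.0909 * 12522 * 0.02 - 108.3) * 1e-9
    assert got == pytest.approx(expect, rel=1e-12)
    assert got == pytest.approx(-22.9, abs=0.05)


def test_delta_omega_cancellation(consts):
    Y = 0.6
    chi_n = consts.chi_ba + consts.psi_Hb * consts.dchi_Hb * (1.0 - Y)
    assert delta_omega(Y, chi_n, consts) == pytest.approx(0.0, abs=1e-12)


@given(Y=st.floats(0.0, 1.0), c=st.floats(0.1, 3.0))
def test_delta_omega_linear_in_one_minus_Y(Y, c):
    consts = PhysioConstants()
    base = delta_omega(1.0, 0.0, consts)
    slope = delta_omega(0.0, 0.0, consts) - base
    assert delta_omega(Y, 0.0, consts) == pytest.approx(base + (1 - Y) * slope,
                                                        rel=1e-9, abs=1e-12)


def test_delta_omega_nonfinite_rejected(consts):
    with pytest.raises(ValueError):
        delta_omega(np.nan, 0.0, consts)


# ---------------------------------------------------------------------------
# fs


def _fs_quad_oracle(x: float) -> float:
    # independent adaptive-quadrature evaluation of
    # (1/3) int_0^1 (2+u) sqrt(1-u) [1 - J0(1.5 x u)] / u^2 du
    def integrand(u):
        if u < 1e-12:
            return (2.0 + u) * np.sqrt(1.0 - u) * (1.5 * x) ** 2 / 4.0
        return (2.0 + u) * np.sqrt(1.0 - u) * (1.0 - j0(1.5 * x * u)) / (u * u)

    val, _ = quad(integrand, 0.0, 1.0, limit=200)
    return val / 3.0


def test_fs_zero_and_even():
    assert fs(0.0) == 0.0
    xs = np.linspace(0.1, 50, 40)
    assert np.allclose(fs(xs), fs(-xs), rtol=0, atol=1e-14)


def test_fs_monotone_nonnegative():
    xs = np.linspace(0.0, 80, 400)
    vals = fs(xs)
    assert np.all(vals >= 0)
    assert np.all(np.diff(vals) >= -1e-12)


def test_fs_small_x_quadratic():
    xs = np.linspace(0.01, 0.3, 15)
    assert np.all(np.abs(fs(xs) / (0.3 * xs ** 2) - 1.0) < 0.02)


def test_fs_large_x_unit_slope():
    for x in (20.0, 40.0):
        slope = (fs(x + 5.0) - fs(x)) / 5.0
        assert slope == pytest.approx(1.0, abs=0.01)


def test_fs_matches_adaptive_quadrature():
    for x in (0.05, 0.5, 2.0, 7.0, 25.0):
        assert fs(x) == pytest.approx(_fs_quad_oracle(x), rel=1e-6)
        assert fs_quadrature(x) == pytest.approx(_fs_quad_oracle(x), rel=1e-8)


def test_fs_prime_odd_and_consistent():
    xs = np.array([0.3, 1.0, 5.0])
    assert np.allclose(fs_prime(-xs), -fs_prime(xs))
    h = 1e-5
    num = (fs(xs + h) - fs(xs - h)) / (2 * h)
    assert np.allclose(fs_prime(xs), num, rtol=1e-4)


# ---------------------------------------------------------------------------
# magnitude model


def test_f_bold_range_and_identity(consts):
    assert f_bold(0.6, 0.0, 0.0, 0.02, consts) == 1.0
    val = f_bold(0.6, 0.03, -10.0, 0.02, consts)
    assert 0.0 < val <= 1.0
    with pytest.raises(ValueError):
        f_bold(0.6, -0.01, 0.0, 0.02, consts)


def test_f_qbold_scaling_and_G(consts, phantom24, acq24):
    truth = phantom24[0]
    mags = f_qbold(truth, acq24, consts)
    assert mags.shape == (8,) + truth.grid_shape
    doubled = ParameterMaps(truth.S0 * 2, truth.R2, truth.Y, truth.v,
                            truth.chi_n, truth.mask)
    assert np.allclose(f_qbold(doubled, acq24, consts), 2 * mags)
    with pytest.raises(ValueError):
        f_qbold(truth, acq24, consts, G=np.full((8,) + truth.grid_shape, 1.5))
    half = f_qbold(truth, acq24, consts, G=0.5)
    assert np.allclose(half, 0.5 * mags)


# ---------------------------------------------------------------------------
# susceptibility model


def test_chi_qsm_hand_value(consts):
    Y, v, chi_n = 0.6, 0.02, -10.0
    blood = (consts.chi_ba / consts.alpha
             + consts.psi_Hb * consts.dchi_Hb
             * (1 - Y - (1 - consts.alpha) * consts.Ya) / consts.alpha)
    assert chi_qsm(Y, v, chi_n, consts) == pytest.approx(
        blood * v + (1 - v / consts.alpha) * chi_n, rel=1e-12)


@given(chi_n=st.floats(-100, 100), v=st.floats(0.0, 0.07))
def test_chi_qsm_linear_in_chi_n(chi_n, v):
    consts = PhysioConstants()
    a = chi_qsm(0.6, v, 0.0, consts)
    slope = 1.0 - v / consts.alpha
    assert chi_qsm(0.6, v, chi_n, consts) == pytest.approx(a + slope * chi_n,
                                                           rel=1e-9, abs=1e-9)


def test_chi_qsm_v_bound(consts):
    with pytest.raises(ValueError):
        chi_qsm(0.6, 0.8, 0.0, consts)


def test_chi_qsm_vs_mixture(consts):
    # printed grouping differs from the exact three-compartment mixture by
    # psi*dchi*(1-alpha)*Y*v/alpha
    Y, v, chi_n = 0.67, 0.023, -11.6
    diff = chi_qsm(Y, v, chi_n, consts) - chi_qsm_mixture(Y, v, chi_n, consts)
    expect = consts.psi_Hb * consts.dchi_Hb * (1 - consts.alpha) * Y * v / consts.alpha
    assert diff == pytest.approx(-expect, rel=1e-9)


# ---------------------------------------------------------------------------
# dipole kernel and field


def test_dipole_kernel_range_and_origin():
    D = dipole_kernel((16, 16, 16))
    assert D[0, 0, 0] == 0.0
    assert D.min() >= -2.0 / 3.0 - 1e-12
    assert D.max() <= 1.0 / 3.0 + 1e-12
    with pytest.raises(ValueError):
        dipole_kernel((1, 16, 16))
    with pytest.raises(ValueError):
        dipole_kernel((16, 16, 16), voxel_size=(0, 1, 1))


def test_uniform_chi_zero_field():
    D = dipole_kernel((12, 12, 12))
    fld = field_from_chi(np.full((12, 12, 12), 7.3), D)
    assert np.max(np.abs(fld)) < 1e-12


def test_field_shape_mismatch():
    D = dipole_kernel((12, 12, 12))
    with pytest.raises(ValueError):
        field_from_chi(np.zeros((8, 8, 8)), D)


def test_chi_from_field_inverts_passband():
    # on k-modes with |D| >= threshold, TKD is the exact inverse of the
    # dipole convolution; inside the cone it is a bounded surrogate
    rng = np.random.default_rng(1)
    shape = (16, 16, 16)
    D = dipole_kernel(shape)
    chi = rng.standard_normal(shape)
    rec = chi_from_field(field_from_chi(chi, D), D, threshold=0.15)
    keep = np.abs(D) >= 0.15
    chi_hat = np.fft.fftn(chi)
    rec_hat = np.fft.fftn(rec)
    assert np.allclose(rec_hat[keep], chi_hat[keep], rtol=1e-8, atol=1e-6)
    with pytest.raises(ValueError):
        chi_from_field(np.zeros(shape), D, threshold=0.9)


# ---------------------------------------------------------------------------
# full forward model


def test_simulate_signal_magnitude_and_phase(phantom24, acq24, consts):
    truth = phantom24[0]
    sig = simulate_signal(truth, acq24, consts)
    assert np.allclose(np.abs(sig.data), f_qbold(truth, acq24, consts))
    chi = np.where(truth.mask, chi_qsm(truth.Y, truth.v, truth.chi_n, consts), 0.0)
    D = dipole_kernel(truth.grid_shape, acq24.voxel_size, acq24.B0_dir)
    fld = field_from_chi(chi, D)
    te = np.asarray(acq24.echo_times)
    expect = acq24.omega0(consts) * te[:, None, None, None] * fld[None] * 1e-9
    m = truth.mask
    assert np.allclose(np.angle(sig.data[:, m]), np.angle(np.exp(1j * expect))[:, m],
                       atol=1e-10)


def test_signal_stack_validation(acq24):
    with pytest.raises(ValueError):
        ComplexSignalStack(np.zeros((3, 24, 24, 24), complex), acq24)
    bad = np.zeros((8, 24, 24, 24), complex)
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        ComplexSignalStack(bad, acq24)


def test_acquisition_validation():
    with pytest.raises(ValueError):
        AcquisitionParams(echo_times=(0.01, 0.005))
    with pytest.raises(ValueError):
        AcquisitionParams(B0_dir=(0, 0, 2))


def test_oef_from_Y():
    assert oef_from_Y(0.98) == pytest.approx(0.0)
    assert oef_from_Y(0.49) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        oef_from_Y(0.5, Ya=0.0)
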