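import numpy as np
import pytest

from mcqq.biophysics import (AcquisitionParams, ParameterMaps, PhysioConstants,
                             dipole_kernel, simulate_signal, ComplexSignalStack)
from mcqq.network import (
    DualUNet,
    LossWeights,
    NetworkConfig,
    NormStats,
    TrainConfig,
    _loss_grad_grad,
    _loss_l1_grad,
    _model_loss_mcqq_grad,
    _model_loss_qq_grad,
    build_network,
    loss_grad,
    loss_l1,
    loss_model_mcqq,
    loss_model_qq,
    predict_sliding,
    prepare_inputs,
    total_loss,
    train,
    z_denormalize,
    z_normalize,
)
from mcqq.phantom import PhantomConfig, make_phantom

SMALL_NET = NetworkConfig(depth=2, base_channels=2, seed=0)


def _toy_params(rng, grid=(8, 8, 8)):
    mask = np.zeros(grid, bool)
    mask[2:6, 2:6, 2:6] = True

    def f(mu, sd, lo, hi):
        return np.where(mask, np.clip(mu + sd * rng.standard_normal(grid), lo, hi), 0.0)

    return ParameterMaps(f(1.1, 0.05, 1.0, 2.0), f(19, 3, 8, 60),
                         f(0.65, 0.05, 0.3, 0.95), f(0.02, 0.005, 0.005, 0.05),
                         f(-10, 20, -200, 150), mask)


# ---------------------------------------------------------------------------
# normalization


def test_z_normalize_round_trip(phantom24):
    truth = phantom24[0]
    stats = NormStats.from_maps([truth])
    z = z_normalize(truth, stats)
    back = z_denormalize(z, stats)
    assert np.max(np.abs(back - truth.stack())) < 1e-12
    m = truth.mask
    assert np.abs(z[:, m].mean(axis=1)).max() < 1e-10
    assert np.abs(z[:, m].std(axis=1) - 1.0).max() < 1e-10


def test_norm_stats_validation():
    with pytest.raises(ValueError):
        NormStats(mean=np.zeros(5), std=np.array([1, 1, 0, 1, 1.0]))


# ---------------------------------------------------------------------------
# losses


def test_loss_l1_examples():
    z = np.zeros((5, 2, 1, 1))
    z2 = z.copy()
    z2[:, 0, 0, 0] = 0.5
    z2[:, 1, 0, 0] = -0.5
    mask = np.ones((2, 1, 1), bool)
    assert loss_l1(z, z, mask) == 0.0
    assert loss_l1(z, z2, mask) == pytest.approx(0.5)
    assert loss_l1(z, z2, mask) == loss_l1(z2, z, mask)
    with pytest.raises(ValueError):
        loss_l1(z, z2[:, :1], mask)


def test_loss_grad_examples():
    mask = np.ones((5, 1, 1), bool)
    a = np.zeros((5, 1, 1))
    # unit step at index 2 versus step at index 3 (displaced edge)
    a[2:] = 1.0
    b = np.zeros((5, 1, 1))
    b[3:] = 1.0
    assert loss_grad(a, a, mask) == 0.0
    assert loss_grad(a, a + 3.0, mask) == 0.0
    # forward-difference maps: da = e_1, db = e_2 -> |diff| sums to 2, /5 voxels
    assert loss_grad(a, b, mask) == pytest.approx(2.0 / 5.0)


def test_loss_gradients_match_fd():
    rng = np.random.default_rng(3)
    mask = rng.random((4, 4, 4)) > 0.3
    zt = rng.standard_normal((5, 4, 4, 4))
    zo = rng.standard_normal((5, 4, 4, 4))
    for fn, t, o in ((_loss_l1_grad, zt, zo), (_loss_grad_grad, zt[2], zo[2])):
        val, g = fn(t, o, mask)
        for _ in range(10):
            i = tuple(rng.integers(0, s) for s in o.shape)
            eps = 1e-6
            op = o.copy()
            op[i] += eps
            om = o.copy()
            om[i] -= eps
            gnum = (fn(t, op, mask)[0] - fn(t, om, mask)[0]) / (2 * eps)
            assert g[i] == pytest.approx(gnum, abs=1e-6)


def test_model_losses_zero_on_equal_and_sensitive(consts):
    rng = np.random.default_rng(0)
    truth = _toy_params(rng)
    acq = AcquisitionParams(grid_shape=truth.grid_shape)
    assert loss_model_mcqq(truth, truth, acq, consts) == 0.0
    assert loss_model_qq(truth, truth, acq, consts) == 0.0
    bumped = ParameterMaps(truth.S0 * 1.01, truth.R2, truth.Y, truth.v,
                           truth.chi_n, truth.mask)
    assert loss_model_mcqq(truth, bumped, acq, consts) > 0
    assert loss_model_qq(truth, bumped, acq, consts) > 0
    chin_b = ParameterMaps(truth.S0, truth.R2, truth.Y, truth.v,
                           np.where(truth.mask, truth.chi_n + 5.0, 0.0), truth.mask)
    assert loss_model_mcqq(truth, chin_b, acq, consts) > 0


def test_model_loss_mask_contract(consts):
    rng = np.random.default_rng(1)
    truth = _toy_params(rng)
    acq = AcquisitionParams(grid_shape=truth.grid_shape)
    relabeled = ParameterMaps(truth.S0 + ~truth.mask * 0.3, truth.R2, truth.Y,
                              truth.v, truth.chi_n, truth.mask)
    # out-of-mask voxels are zero-filled internally, so relabeling them
    # outside the mask changes nothing
    assert loss_model_mcqq(truth, relabeled, acq, consts) == pytest.approx(0.0, abs=1e-15)
    assert loss_model_qq(truth, relabeled, acq, consts) == pytest.approx(0.0, abs=1e-15)


def test_model_loss_gradients_match_fd(consts):
    rng = np.random.default_rng(2)
    truth = _toy_params(rng)
    acq = AcquisitionParams(grid_shape=truth.grid_shape)
    kernel = dipole_kernel(truth.grid_shape, acq.voxel_size, acq.B0_dir)
    t = truth.stack()
    o = t + np.where(truth.mask[None], 0.01 * (np.abs(t) + 0.01)
                     * rng.standard_normal(t.shape), 0.0)
    idx = list(zip(*np.where(truth.mask)))
    for fn in (lambda x: _model_loss_mcqq_grad(x, t, truth.mask, acq, consts, kernel),
               lambda x: _model_loss_qq_grad(x, t, truth.mask, acq, consts)):
        _, g = fn(o)
        for _ in range(8):
            p = rng.integers(0, 5)
            i = (p,) + idx[rng.integers(0, len(idx))]
            eps = 1e-6 * max(abs(o[i]), 1.0)
            op = o.copy()
            op[i] += eps
            om = o.copy()
            om[i] -= eps
            gnum = (fn(op)[0] - fn(om)[0]) / (2 * eps)
            assert g[i] == pytest.approx(gnum, rel=1e-3, abs=1e-10)


def test_phase_pathway_distinguishes_arrangements(consts):
    """A chi_n swap leaves the qq loss geometry-blind but moves the mcqq loss.

    With v = 0 the magnitude is independent of chi_n, so swapping chi_n
    between two voxels is a pure-phase perturbation.  The per-voxel qq loss
    gives the same value whichever voxel pair is swapped; the mcqq loss
    differs between a swap along B0 and a swap across B0 because the
    dipole-convolved phase is anisotropic.
    """
    grid = (12, 12, 12)
    acq = AcquisitionParams(grid_shape=grid)
    base = {"S0": 1.2, "R2": 20.0, "Y": 0.6, "chi_n": 0.0}

    def params(chi_pairs):
        mask = np.zeros(grid, bool)
        arrs = {k: np.zeros(grid) for k in ("S0", "R2", "Y", "v", "chi_n")}
        for (pos, chin) in chi_pairs:
            mask[pos] = True
            for k, val in base.items():
                arrs[k][pos] = val
            arrs["chi_n"][pos] = chin
        return ParameterMaps(arrs["S0"], arrs["R2"], arrs["Y"], arrs["v"],
                             arrs["chi_n"], mask)

    c = 6
    along = [((c, c, c - 2), 40.0), ((c, c, c + 2), -40.0)]
    across = [((c - 2, c, c), 40.0), ((c + 2, c, c), -40.0)]
    for pair in (along, across):
        truth = params(pair)
        swapped = params([(pair[0][0], pair[1][1]), (pair[1][0], pair[0][1])])
        qq_a = loss_model_qq(truth, swapped, acq, consts)
        mc_a = loss_model_mcqq(truth, swapped, acq, consts)
        if pair is along:
            qq_along, mc_along = qq_a, mc_a
    # per-voxel loss cannot tell the two geometries apart
    assert qq_along == pytest.approx(qq_a, rel=1e-12)
    # the convolved-phase loss can
    assert abs(mc_along - mc_a) > 0.1 * max(mc_along, mc_a)


def test_total_loss_weights():
    assert total_loss(1, 0, 0) == 1.0
    assert total_loss(0, 1, 1) == pytest.approx(0.2)
    assert total_loss(1, 1, 1) == pytest.approx(1.2)
    assert total_loss(1, 1, 1, LossWeights(w_model=0.5, w_grad=0.0)) == 1.5
    with pytest.raises(ValueError):
        total_loss(-1, 0, 0)
    with pytest.raises(ValueError):
        LossWeights(w_model=-0.1)


# ---------------------------------------------------------------------------
# architecture


def test_network_config_validation():
    with pytest.raises(ValueError):
        NetworkConfig(conv_kernel=5)
    with pytest.raises(ValueError):
        NetworkConfig(depth=0)
    with pytest.raises(ValueError):
        NetworkConfig(out_channels_magnitude=4)


def test_layer_count_formula():
    for depth in (1, 2, 4):
        cfg = NetworkConfig(depth=depth, base_channels=2)
        model = build_network(cfg)
        expected = {"conv3": 4 * depth + 2, "pool": depth, "deconv": depth,
                    "concat": depth, "conv1": 1}
        assert model.layer_counts() == expected
        assert model.phase_net.layer_counts() == expected


def test_layer_count_invariant_enforced(monkeypatch):
    import mcqq.network as nw

    def broken(self):
        return {"conv3": 17, "pool": 4, "deconv": 4, "concat": 4, "conv1": 1}

    monkeypatch.setattr(nw._UNet, "layer_counts", broken)
    with pytest.raises(RuntimeError):
        build_network(NetworkConfig(depth=2, base_channels=2))


def test_forward_shape_and_bounds():
    model = build_network(SMALL_NET)
    rng = np.random.default_rng(1)
    out = model.forward(rng.standard_normal((8, 8, 8, 4)),
                        rng.standard_normal((8, 8, 8, 4)))
    assert out.shape == (5, 8, 8, 4)
    assert np.all(out > model.lo[:, None, None, None])
    assert np.all(out < model.hi[:, None, None, None])


def test_merge_degenerate_weights():
    model = build_network(SMALL_NET)
    rng = np.random.default_rng(2)
    xm = rng.standard_normal((8, 4, 4, 4))
    xp = rng.standard_normal((8, 4, 4, 4))
    model.merge.params["w_mag"][:] = 1.0
    model.merge.params["w_phase"][:] = 0.0
    model.forward(xm, xp)
    merged = model.merge.forward2(model._pre_mag, model._pre_phase)
    assert np.allclose(merged[2:], model._pre_mag[2:])
    assert np.allclose(merged[:2], model._pre_mag[:2])


def test_checkpoint_state_round_trip():
    model = build_network(SMALL_NET)
    state = model.get_state()
    model2 = build_network(NetworkConfig(depth=2, base_channels=2, seed=99))
    model2.set_state(state)
    rng = np.random.default_rng(3)
    xm = rng.standard_normal((8, 4, 4, 4))
    xp = rng.standard_normal((8, 4, 4, 4))
    assert np.array_equal(model.forward(xm, xp), model2.forward(xm, xp))


# ---------------------------------------------------------------------------
# training and prediction


@pytest.fixture(scope="module")
def train_setup():
    grid = (24, 24, 16)
    acq = AcquisitionParams(grid_shape=grid)
    brains = [make_phantom(PhantomConfig(grid_shape=grid, seed=s, smoothness=3.0))[0]
              for s in (0, 1)]
    return acq, brains


def test_train_decreases_loss_and_is_deterministic(train_setup, consts):
    acq, brains = train_setup
    tc = TrainConfig(epochs=8, lr=1e-2, patch_shape=(16, 16, 8), seed=0)
    model = build_network(NetworkConfig(depth=2, base_channels=4, seed=0))
    res = train(model, brains, acq, consts, tc, val_brains=brains[:1])
    assert res["epoch_loss"][-1] < res["epoch_loss"][0]
    assert res["val_l1"][-1] < res["val_l1"][0]
    model2 = build_network(NetworkConfig(depth=2, base_channels=4, seed=0))
    res2 = train(model2, brains, acq, consts, tc, val_brains=brains[:1])
    assert np.array_equal(res["history"], res2["history"])


def test_train_lr_zero_constant_validation(train_setup, consts):
    acq, brains = train_setup
    model = build_network(NetworkConfig(depth=2, base_channels=2, seed=0))
    state0 = model.get_state()
    tc = TrainConfig(epochs=3, lr=0.0, patch_shape=(16, 16, 8), seed=0)
    res = train(model, brains, acq, consts, tc, val_brains=brains[:1])
    assert np.all(res["val_l1"] == res["val_l1"][0])
    state1 = model.get_state()
    assert all(np.array_equal(state0[k], state1[k]) for k in state0)


def test_train_nan_aborts_with_diagnostic(train_setup, consts):
    acq, brains = train_setup
    model = build_network(NetworkConfig(depth=2, base_channels=2, seed=0))
    model.mag_net.final.params["W"][...] = np.nan
    with pytest.raises(RuntimeError, match="diverged"):
        train(model, brains, acq, consts,
              TrainConfig(epochs=1, patch_shape=(16, 16, 8)))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(batch_size=2)
    with pytest.raises(ValueError):
        TrainConfig(model_loss="other")
    with pytest.raises(ValueError):
        TrainConfig(lr=-1.0)


def test_prepare_inputs_constant_channel():
    mags = np.full((8, 4, 4, 4), 0.7)
    phases = np.zeros((8, 4, 4, 4))
    zm, zp = prepare_inputs(mags, phases, np.ones((4, 4, 4), bool))
    assert np.max(np.abs(zm)) < 1e-12
    assert np.max(np.abs(zp)) < 1e-12


def test_predict_sliding_coverage_and_bounds(train_setup, consts):
    acq, brains = train_setup
    truth = brains[0]
    sig = simulate_signal(truth, acq, consts)
    model = build_network(NetworkConfig(depth=2, base_channels=2, seed=0))
    params, cov = predict_sliding(model, sig, truth.mask, patch_shape=(16, 16, 8),
                                  overlap=0.3, return_coverage=True)
    assert cov.min() >= 1.0
    th = params.stack()[:, truth.mask]
    assert np.all(th > model.lo[:, None]) and np.all(th < model.hi[:, None])
    with pytest.raises(ValueError):
        predict_sliding(model, sig, truth.mask, overlap=0.95)


def test_predict_sliding_constant_input(train_setup, consts):
    acq, _ = train_setup
    grid = acq.grid_shape
    sig = ComplexSignalStack(np.full((8,) + tuple(grid), 0.5 + 0j), acq)
    model = build_network(NetworkConfig(depth=2, base_channels=2, seed=0))
    params = predict_sliding(model, sig, np.ones(grid, bool),
                             patch_shape=(16, 16, 8), overlap=0.3)
    st = params.stack()
    assert max(float(np.ptp(st[i])) for i in range(5)) < 1e-8


def test_predict_sliding_single_patch_fallback(consts):
    grid = (10, 10, 10)
    acq = AcquisitionParams(grid_shape=grid)
    rng = np.random.default_rng(4)
    data = 0.5 + 0.1 * rng.standard_normal((8,) + grid) \
        + 1j * 0.05 * rng.standard_normal((8,) + grid)
    sig = ComplexSignalStack(data, acq)
    model = build_network(NetworkConfig(depth=2, base_channels=2, seed=0))
    params = predict_sliding(model, sig, np.ones(grid, bool),
                             patch_shape=(16, 16, 16), overlap=0.3)
    assert params.grid_shape == grid
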