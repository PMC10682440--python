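"""Tests of the lifted linear surrogate: dictionary features, EDMD exactness
on linear data, nested-residual monotonicity and the Taylor baseline."""

import numpy as np
import pytest

from bcgdose import koopman as kp
from bcgdose.model import ImpulseSchedule, ModelParameters, ode_rhs


class TestThinPlateRBF:
    def test_unit_distance_is_zero(self):
        center = np.zeros((1, kp.EXT_DIM))
        z = np.zeros(kp.EXT_DIM)
        z[0] = 1.0
        assert kp.thin_plate_rbf(z, center)[0] == pytest.approx(0.0, abs=1e-15)

    def test_distance_e(self):
        center = np.zeros((1, kp.EXT_DIM))
        z = np.zeros(kp.EXT_DIM)
        z[0] = np.e
        assert kp.thin_plate_rbf(z, center)[0] == pytest.approx(np.e**2, rel=1e-12)

    def test_at_center_is_zero_by_limit(self):
        c = np.arange(kp.EXT_DIM, dtype=float)
        assert kp.thin_plate_rbf(c, c[None, :])[0] == 0.0


class TestExtendedStates:
    def test_layout_and_length(self):
        y = np.arange(10.0)
        u = np.arange(10.0) * 10
        z = kp.extended_states(y, u)
        assert z.shape == (8, kp.EXT_DIM)
        # Z_k = [y_k, y_{k-1}, y_{k-2}, u_{k-1}, u_{k-2}] at k = 2
        np.testing.assert_array_equal(z[0], [2.0, 1.0, 0.0, 10.0, 0.0])

    def test_lifted_dimension_with_defaults(self, koopman_model):
        assert kp.EXT_DIM == 5
        assert koopman_model.lifted_dim == 15


class TestGenerateTrainingData:
    def test_seeded_determinism(self, params):
        a = kp.generate_training_data(params, n_traj=3, horizon_days=10, seed=1)
        b = kp.generate_training_data(params, n_traj=3, horizon_days=10, seed=1)
        for ta, tb in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(ta.y, tb.y)
            np.testing.assert_array_equal(ta.u, tb.u)

    def test_doses_within_admissible_range(self, params):
        ds = kp.generate_training_data(params, n_traj=5, horizon_days=20, seed=2)
        for t in ds.trajectories:
            assert t.u.min() >= 0.0 and t.u.max() <= 6.4

    def test_trajectory_count(self, params):
        ds = kp.generate_training_data(params, n_traj=7, horizon_days=10, seed=3)
        assert len(ds.trajectories) == 7


class TestFitCenters:
    def test_single_center_is_mean(self, arx_dataset):
        ds, _, _ = arx_dataset
        centers = kp.fit_centers(ds, k=1, seed=0)
        pooled = np.vstack([kp.extended_states(t.y, t.u) for t in ds.trajectories])
        np.testing.assert_allclose(centers[0], pooled.mean(axis=0), rtol=1e-6)

    def test_separated_blobs_recovered(self):
        rng = np.random.default_rng(4)
        blobs = [rng.normal(c, 0.05, size=(200, kp.EXT_DIM))
                 for c in (-5.0, 0.0, 5.0)]
        y = np.zeros(10)  # unused; feed pooled states via a fake dataset
        pooled = np.vstack(blobs)
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(pooled)
        got = np.sort(km.cluster_centers_[:, 0])
        np.testing.assert_allclose(got, [-5.0, 0.0, 5.0], atol=0.2)

    def test_too_many_clusters_rejected(self, arx_dataset):
        ds, _, _ = arx_dataset
        with pytest.raises(ValueError):
            kp.fit_centers(ds, k=10**6)

    def test_seeded_determinism(self, arx_dataset):
        ds, _, _ = arx_dataset
        a = kp.fit_centers(ds, k=4, seed=5)
        b = kp.fit_centers(ds, k=4, seed=5)
        np.testing.assert_array_equal(a, b)


class TestEDMD:
    def test_exact_recovery_of_linear_system(self, arx_dataset):
        ds, a_true, b_true = arx_dataset
        model = kp.fit_koopman(ds, centers=None)
        np.testing.assert_allclose(model.a, a_true, atol=1e-8)
        np.testing.assert_allclose(model.b, b_true, atol=1e-8)
        # one-step residual on the training data
        z = kp.extended_states(ds.trajectories[0].y, ds.trajectories[0].u)
        u = ds.trajectories[0].u[2:-1]
        pred = z[:-1] @ model.a.T + np.outer(u, model.b)
        assert np.abs(pred - z[1:]).max() < 1e-10

    def test_multi_step_prediction_exact_on_linear_data(self, arx_dataset):
        ds, _, _ = arx_dataset
        model = kp.fit_koopman(ds, centers=None)
        t = ds.trajectories[1]
        z = kp.extended_states(t.y, t.u)
        xhat = kp.predict(model, z[0], t.u[2:], steps=100)
        np.testing.assert_allclose(xhat[:, 0], t.y[2:103], atol=1e-8)

    def test_rbf_features_never_increase_training_residual(self, params):
        """Nested least squares: predicting the next extended state from the
        RBF-augmented regressor can never fit worse than from the plain one."""
        ds = kp.generate_training_data(params, n_traj=5, horizon_days=20, seed=6)
        centers = kp.fit_centers(ds, k=5, seed=6)
        _, z_next, _, _ = kp._training_arrays(ds, None)

        def residual(centers_):
            zl, _, u, _ = kp._training_arrays(ds, centers_)
            reg = np.hstack([zl, u[:, None]])
            theta = np.linalg.lstsq(reg, z_next, rcond=None)[0]
            return np.linalg.norm(reg @ theta - z_next)

        assert residual(centers) <= residual(None) + 1e-9

    def test_zero_step_prediction_is_projection(self, arx_dataset):
        ds, _, _ = arx_dataset
        model = kp.fit_koopman(ds, centers=None)
        z0 = kp.extended_states(ds.trajectories[0].y, ds.trajectories[0].u)[0]
        out = kp.predict(model, z0, np.empty(0), steps=0)
        assert out.shape == (1, 4)
        np.testing.assert_allclose(out[0], model.c @ z0, rtol=1e-12)

    def test_one_step_error_below_rollout_error(self, params, koopman_model,
                                                held_out_run):
        t = held_out_run
        z = kp.extended_states(t.y, t.u)
        zl = koopman_model.lift(z)
        one_step = zl[:-1] @ koopman_model.a.T \
            + np.outer(t.u[2:-1], koopman_model.b)
        one_step_tu = (one_step @ koopman_model.c.T)[:, 3]
        one_err = np.sqrt(np.mean((one_step_tu - t.y[3:]) ** 2))
        rollout = kp.predict(koopman_model, z[0], t.u[2:], steps=z.shape[0] - 1)
        roll_err = np.sqrt(np.mean((rollout[1:, 3] - t.y[3:]) ** 2))
        assert one_err <= roll_err


class TestTaylorLinearization:
    def test_jacobian_structure_at_origin(self, params):
        jac, offset = kp.taylor_linearize(params, np.zeros(4))
        expected = np.diag([-params.mu1, -params.mu2, 0.0, params.r])
        expected[1, 2] = params.alpha
        np.testing.assert_allclose(jac, expected, atol=1e-14)
        np.testing.assert_allclose(offset, np.zeros(4), atol=1e-14)

    def test_jacobian_matches_central_differences(self, params):
        x = np.array([0.4, 0.3, 0.2, 0.9])
        jac, _ = kp.taylor_linearize(params, x)
        h = 1e-6
        fd = np.empty((4, 4))
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            fd[:, j] = (ode_rhs(x + e, params) - ode_rhs(x - e, params)) / (2 * h)
        np.testing.assert_allclose(jac, fd, atol=1e-6)

    def test_affine_simulation_exact_for_linear_dynamics(self, params):
        # a linear test system: dx/dt = J x with diagonal decay
        jac = np.diag([-1.0, -0.5, -0.2, -0.1])
        sched = ImpulseSchedule([0, 50], [2.0, 1.0], dt=0.01, kt=100)
        out = kp.simulate_affine(jac, np.zeros(4), np.zeros(4), sched)
        # impulse at 0 puts mass on B; exact solution is 2*exp(-t) then +1 jump
        t1 = 0.5
        assert out[50, 0] == pytest.approx(2 * np.exp(-t1) + 1.0, rel=1e-9)

    def test_koopman_beats_taylor_on_held_out_run(self, params, koopman_model,
                                                  held_out_run):
        t = held_out_run
        z = kp.extended_states(t.y, t.u)
        pred = kp.predict(koopman_model, z[0], t.u[2:], steps=z.shape[0] - 1)
        rmse_koopman = np.sqrt(np.mean((pred[:, 3] - t.y[2:]) ** 2))

        jac, off = kp.taylor_linearize(params, t.x[0])
        idx = np.flatnonzero(t.u > 0)
        sched = ImpulseSchedule(idx, t.u[idx], kt=t.u.size - 1)
        x0 = t.x[0].copy()
        x0[0] -= t.u[0]
        lin = kp.simulate_affine(jac, off, x0, sched)
        rmse_taylor = np.sqrt(np.mean((lin[2:, 3] - t.y[2:]) ** 2))
        assert rmse_koopman < rmse_taylor


class TestSerialization:
    def test_save_load_roundtrip(self, tmp_path, arx_dataset):
        ds, _, _ = arx_dataset
        model = kp.fit_koopman(ds, centers=None)
        path = tmp_path / "model.json"
        model.save(path)
        back = kp.KoopmanModel.load(path)
        np.testing.assert_array_equal(back.a, model.a)
        np.testing.assert_array_equal(back.b, model.b)
        np.testing.assert_array_equal(back.c, model.c)
        assert back.centers is None
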