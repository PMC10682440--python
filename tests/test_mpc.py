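"""Tests of the MPC layer: Riccati terminal weight, prediction structure,
the active-set QP against oracles, and closed-loop sanity properties."""

import numpy as np
import pytest

from bcgdose import koopman as kp
from bcgdose import mpc
from bcgdose.model import ModelParameters, X0_DEFAULT, settling_time, simulate


class TestDARE:
    def test_scalar_closed_form(self):
        # P = a^2 P - (aPb)^2/(b^2 P + r) + q reduces to P^2 - 0.25P - 1 = 0
        p = mpc.solve_dare(0.5, 1.0, 1.0, 1.0)
        expected = (0.25 + np.sqrt(0.0625 + 4.0)) / 2.0
        assert p[0, 0] == pytest.approx(expected, abs=1e-6)
        assert p[0, 0] == pytest.approx(1.13278, abs=1e-5)

    def test_deadbeat_case(self):
        q = np.diag([1.0, 2.0])
        p = mpc.solve_dare(np.zeros((2, 2)), np.eye(2), q, np.eye(2))
        np.testing.assert_allclose(p, q, atol=1e-10)

    def test_random_stabilizable_instance_residual(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 5))
        a *= 0.9 / np.abs(np.linalg.eigvals(a)).max()  # stable => stabilizable
        b = rng.normal(size=(5, 2))
        q = np.eye(5)
        r = np.eye(2)
        p = mpc.solve_dare(a, b, q, r)
        gain = np.linalg.solve(b.T @ p @ b + r, b.T @ p @ a)
        res = a.T @ p @ a - a.T @ p @ b @ gain + q - p
        assert np.linalg.norm(res) < 1e-8
        assert np.all(np.linalg.eigvalsh(p) > -1e-10)


def tiny_model():
    """A hand-built 2-state lifted model for structural checks."""
    a = np.array([[0.9, 0.1], [0.0, 0.8]])
    b = np.array([1.0, 0.5])
    c = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
    return kp.KoopmanModel(a=a, b=b, c=c, centers=None)


class TestPrediction:
    def test_single_step_structure(self):
        m = tiny_model()
        w, g = mpc.build_prediction(m, hp_steps=1, control_interval_steps=1)
        np.testing.assert_allclose(w, m.a)
        np.testing.assert_allclose(g[:, 0], m.b)

    def test_non_move_columns_are_zero(self):
        m = tiny_model()
        _, g = mpc.build_prediction(m, hp_steps=6, control_interval_steps=3,
                                    n_moves=2)
        nonzero_cols = np.flatnonzero(np.abs(g).sum(axis=0))
        np.testing.assert_array_equal(nonzero_cols, [0, 3])

    def test_identity_dynamics_stack_constant(self):
        m = kp.KoopmanModel(a=np.eye(2), b=np.array([1.0, 0.0]),
                            c=np.zeros((4, 2)), centers=None)
        _, g = mpc.build_prediction(m, hp_steps=4, control_interval_steps=1)
        # move column: e1 repeated in every block row
        col = g[:, 0].reshape(4, 2)
        np.testing.assert_allclose(col, np.tile([1.0, 0.0], (4, 1)))

    def test_horizon_shorter_than_moves_rejected(self):
        with pytest.raises(ValueError):
            mpc.build_prediction(tiny_model(), hp_steps=2,
                                 control_interval_steps=5, n_moves=2)


def brute_force_qp(qp, lo, hi, resolution=1e-3):
    """Grid-search oracle for 1-D QPs."""
    grid = np.arange(lo, hi + resolution, resolution)
    vals = qp.h[0, 0] * grid**2 + 2 * qp.f[0] * grid
    return grid[int(np.argmin(vals))]


class TestQP:
    def test_clipped_unconstrained_optimum(self):
        # min (u-3)^2 = u^2 - 6u + 9 subject to 0 <= u <= 2
        qp = mpc.QPProblem(h=np.array([[1.0]]), f=np.array([-3.0]),
                           a_ineq=np.array([[1.0], [-1.0]]),
                           b_ineq=np.array([2.0, 0.0]))
        u, lam = mpc.solve_qp(qp)
        assert u[0] == pytest.approx(2.0, abs=1e-10)
        assert mpc.kkt_residual(qp, u, lam) < 1e-6

    def test_inactive_constraints_match_unconstrained(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(3, 3))
        h = m @ m.T + np.eye(3)
        f = rng.normal(size=3)
        qp = mpc.QPProblem(h=h, f=f,
                           a_ineq=np.vstack([np.eye(3), -np.eye(3)]),
                           b_ineq=np.full(6, 100.0))
        u, lam = mpc.solve_qp(qp)
        np.testing.assert_allclose(u, np.linalg.solve(h, -f), atol=1e-8)
        assert mpc.kkt_residual(qp, u, lam) < 1e-6

    @pytest.mark.parametrize("seed", range(5))
    def test_random_box_qp_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        h = np.array([[rng.uniform(0.5, 3.0)]])
        f = np.array([rng.uniform(-5.0, 5.0)])
        lo, hi = sorted(rng.uniform(-2.0, 2.0, size=2))
        qp = mpc.QPProblem(h=h, f=f, a_ineq=np.array([[1.0], [-1.0]]),
                           b_ineq=np.array([hi, -lo]))
        u, lam = mpc.solve_qp(qp)
        oracle = brute_force_qp(qp, lo, hi)
        assert abs(u[0] - oracle) <= 1e-3
        assert mpc.kkt_residual(qp, u, lam) < 1e-6

    def test_infeasible_reported(self):
        qp = mpc.QPProblem(h=np.eye(1), f=np.zeros(1),
                           a_ineq=np.array([[1.0], [-1.0]]),
                           b_ineq=np.array([-1.0, -1.0]))  # u <= -1 and u >= 1
        with pytest.raises(RuntimeError, match="infeasible"):
            mpc.solve_qp(qp)


class TestBuildQP:
    def test_hessian_symmetric_psd(self, koopman_model):
        cfg = mpc.MPCConfig()
        q_lift = koopman_model.c.T @ np.diag(cfg.q_diag) @ koopman_model.c
        z = koopman_model.lift(np.array([0.8, 0.8, 0.8, 0.0, 0.0]))
        qp = mpc.build_qp(koopman_model, cfg, z, np.full(500, 0.1), q_lift)
        np.testing.assert_allclose(qp.h, qp.h.T, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(qp.h) > 0)

    def test_zero_state_zero_reference_gives_zero_move(self):
        # linear model with no RBF features: the lifted origin is invariant
        m = tiny_model()
        cfg = mpc.MPCConfig(horizon_days=0.05, control_interval_days=0.01)
        p = np.eye(2)
        qp = mpc.build_qp(m, cfg, np.zeros(2), np.zeros(5), p)
        u, _ = mpc.solve_qp(qp)
        assert u[0] == pytest.approx(0.0, abs=1e-12)


class TestClosedLoop:
    def test_disabled_controller_reproduces_untreated(self, params, koopman_model):
        cfg = mpc.MPCConfig(u_max=0.0)
        traj, doses = mpc.run_receding_horizon(params, X0_DEFAULT, koopman_model,
                                               cfg, horizon_days=20.0)
        assert np.all(doses == 0.0)
        untreated = simulate(params, X0_DEFAULT, kt=2000)
        np.testing.assert_array_equal(traj.states, untreated.states)

    def test_doses_within_box(self, params, koopman_model):
        traj, doses = mpc.run_receding_horizon(params, X0_DEFAULT, koopman_model)
        assert np.all(doses >= 0.0) and np.all(doses <= 6.4 + 1e-12)

    def test_settles_within_35_days(self, params, koopman_model):
        traj, doses = mpc.run_receding_horizon(params, X0_DEFAULT, koopman_model)
        st = settling_time(traj)
        assert st is not None and st < 35.0

    def test_front_loaded_versus_regimen_schedule(self, params, koopman_model):
        """The closed loop doses aggressively early relative to the flat
        regimen dose."""
        _, doses = mpc.run_receding_horizon(params, X0_DEFAULT, koopman_model)
        assert doses[0] > 5.46
        assert doses[:3].mean() > doses[3:].mean()

    def test_deterministic_given_model(self, params, koopman_model):
        t1, d1 = mpc.run_receding_horizon(params, X0_DEFAULT, koopman_model,
                                          horizon_days=30.0)
        t2, d2 = mpc.run_receding_horizon(params, X0_DEFAULT, koopman_model,
                                          horizon_days=30.0)
        np.testing.assert_array_equal(d1, d2)
        np.testing.assert_array_equal(t1.states, t2.states)


class TestLQRConsistency:
    def test_one_step_mpc_with_dare_terminal_is_lqr(self):
        """With the DARE solution as terminal weight, the one-step Bellman
        problem min_u uRu + (Az+Bu)'P(Az+Bu) recovers the stationary LQR
        feedback exactly on a linear plant."""
        a = np.array([[1.05, 0.1], [0.0, 0.9]])
        b = np.array([0.5, 1.0])
        c = np.vstack([np.eye(2), np.zeros((2, 2))])  # states observed directly
        model = kp.KoopmanModel(a=a, b=b, c=c, centers=None)
        q4 = np.diag([1.0, 1.0, 0.0, 0.0])
        q = c.T @ q4 @ c
        r = 0.1
        p = mpc.solve_dare(a, b, q, np.atleast_2d(r))
        k_lqr = np.linalg.solve(b[None, :] @ p @ b[:, None] + r,
                                b[None, :] @ p @ a)[0]

        cfg = mpc.MPCConfig(horizon_days=0.01, control_interval_days=0.01,
                            q_diag=(1.0, 1.0, 0.0, 0.0), r_weight=r,
                            u_min=-1e6, u_max=1e6)
        for z in ([1.0, 0.3], [-0.5, 0.8], [2.0, -1.0]):
            z = np.array(z)
            qp = mpc.build_qp(model, cfg, z, np.zeros(1), p)
            u, _ = mpc.solve_qp(qp)
            assert u[0] == pytest.approx(-k_lqr @ z, abs=1e-4)
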