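"""Controller contracts: PID, redundancy QP, overcompensation, MPC, loops."""

import numpy as np
import pytest
from scipy.linalg import expm

from fesreach.arm_model import ArmState
from fesreach.controllers import (
    LinearizedDiscreteModel,
    MpcConfig,
    PidGains,
    linearize_discretize,
    mpc_step,
    overcompensation_fallback,
    pid_feedback_torque,
    resolve_activations_qp,
    run_closed_loop,
    zoh_discretize,
)
from fesreach.muscle_capability import torque_achievable
from fesreach.planning import quintic_direct_trajectory


# ---------------------------------------------------------------------------
# PID
# ---------------------------------------------------------------------------


class TestPid:
    def test_zero_error_zero_torque(self):
        x = ArmState(np.ones(4), np.zeros(4))
        integral = np.zeros(4)
        tau = pid_feedback_torque(x, x, PidGains(), integral, 0.02)
        assert np.all(tau == 0.0)
        assert np.all(integral == 0.0)

    def test_pure_proportional(self):
        gains = PidGains(kp=10.0, kd=0.0, ki=0.0)
        x = ArmState(np.zeros(4), np.zeros(4))
        ref = ArmState(np.array([0.1, -0.2, 0.3, 0.0]), np.zeros(4))
        tau = pid_feedback_torque(x, ref, gains, np.zeros(4), 0.02)
        assert np.allclose(tau, 10.0 * (ref.q - x.q))

    def test_integral_accumulates_error_times_dt(self):
        gains = PidGains(kp=0.0, kd=0.0, ki=1.0, integral_limit=100.0)
        x = ArmState(np.zeros(4), np.zeros(4))
        e = np.array([0.1, 0.0, -0.1, 0.05])
        ref = ArmState(e, np.zeros(4))
        integral = np.zeros(4)
        dt = 0.02
        for _ in range(7):
            pid_feedback_torque(x, ref, gains, integral, dt)
        assert np.allclose(integral, 7 * e * dt)

    def test_anti_windup_clamps(self):
        gains = PidGains(integral_limit=0.01)
        x = ArmState(np.zeros(4), np.zeros(4))
        ref = ArmState(np.ones(4), np.zeros(4))
        integral = np.zeros(4)
        for _ in range(100):
            pid_feedback_torque(x, ref, gains, integral, 0.02)
        assert np.all(np.abs(integral) <= 0.01 + 1e-15)

    def test_negative_gains_rejected(self):
        with pytest.raises(ValueError):
            PidGains(kp=-1.0)


# ---------------------------------------------------------------------------
# redundancy QP and fallback
# ---------------------------------------------------------------------------


def _enumerate_min_norm(R, tau, tol=1e-7):
    """Brute-force oracle: enumerate bound-active sets, keep the best."""
    n = R.shape[1]
    best = None
    for free_mask in range(2**n):
        free = [i for i in range(n) if (free_mask >> i) & 1]
        fixed = [i for i in range(n) if i not in free]
        RF = R[:, free] if free else np.zeros((R.shape[0], 0))
        pinv = np.linalg.pinv(RF) if free else None
        n_fix = len(fixed)
        combos = (
            np.array(
                np.meshgrid(*([[0.0, 1.0]] * n_fix), indexing="ij")
            ).reshape(n_fix, -1).T
            if n_fix
            else np.zeros((1, 0))
        )
        rhs = tau[None, :] - combos @ R[:, fixed].T
        for b, r in zip(combos, rhs):
            if free:
                aF = pinv @ r
                if np.linalg.norm(RF @ aF - r) > tol:
                    continue
                if np.any(aF < -1e-9) or np.any(aF > 1 + 1e-9):
                    continue
            else:
                if np.linalg.norm(r) > tol:
                    continue
                aF = np.zeros(0)
            a = np.zeros(n)
            a[free] = aF
            a[fixed] = b
            obj = a @ a
            if best is None or obj < best:
                best = obj
    return best


class TestRedundancyQp:
    def test_orthogonal_columns_unique_solution(self):
        R = np.zeros((4, 9))
        scale = np.array([2.0, 1.0, 0.5, 4.0])
        R[np.arange(4), np.arange(4)] = scale
        tau = np.array([0.5, 0.2, 0.1, 1.0])
        alpha, ok = resolve_activations_qp(R, tau)
        assert ok
        assert np.allclose(alpha[:4], tau / scale, atol=1e-7)
        assert np.allclose(alpha[4:], 0.0, atol=1e-8)

    def test_identical_columns_split_load(self):
        """Two equal columns able to produce tau share it equally
        (minimum-norm solution of the KKT system)."""
        R = np.zeros((4, 9))
        col = np.array([1.0, 0.5, 0.0, 0.0])
        R[:, 2] = col
        R[:, 7] = col
        tau = 0.8 * col
        alpha, ok = resolve_activations_qp(R, tau)
        assert ok
        assert alpha[2] == pytest.approx(0.4, abs=1e-6)
        assert alpha[7] == pytest.approx(0.4, abs=1e-6)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            R = rng.normal(0, 1, (4, 9))
            tau = R @ rng.uniform(0, 1, 9)
            alpha, ok = resolve_activations_qp(R, tau)
            assert ok
            best = _enumerate_min_norm(R, tau)
            assert alpha @ alpha == pytest.approx(best, abs=1e-6)

    def test_unachievable_torque_flagged(self):
        rng = np.random.default_rng(4)
        R = np.abs(rng.normal(0, 1, (4, 9)))   # only non-negative torques
        tau = np.array([-1.0, -1.0, -1.0, -1.0])
        assert not torque_achievable(R, tau)
        alpha, ok = resolve_activations_qp(R, tau)
        assert not ok
        assert np.all(alpha == 0.0)

    def test_feedforward_shifts_the_box(self):
        R = np.zeros((4, 9))
        R[0, 0] = 1.0
        alpha_ff = np.zeros(9)
        alpha_ff[0] = 0.9
        # requesting 0.2 would exceed the remaining headroom of muscle 0
        alpha, ok = resolve_activations_qp(R, np.array([0.2, 0, 0, 0]), alpha_ff)
        assert not ok
        alpha, ok = resolve_activations_qp(R, np.array([0.05, 0, 0, 0]), alpha_ff)
        assert ok
        assert alpha[0] == pytest.approx(0.05, abs=1e-7)


class TestOvercompensation:
    def test_feasible_request_passes_through(self):
        R = np.zeros((4, 9))
        R[np.arange(4), np.arange(4)] = 1.0
        tau = np.array([0.3, 0.1, 0.0, 0.2])
        direct, _ = resolve_activations_qp(R, tau)
        via_fallback, info = overcompensation_fallback(R, tau)
        assert not info["exhausted"]
        assert info["scale"] == 1.0
        assert np.allclose(direct, via_fallback)

    def test_shrinks_until_inside_polytope(self):
        """Request 3x the reachable magnitude: feasibility first occurs at
        0.7^4 = 0.2401 < 1/3, and the direction is preserved."""
        R = np.zeros((4, 9))
        R[np.arange(4), np.arange(4)] = 1.0
        d = np.array([1.0, 0.0, 0.0, 0.0])
        tau = 3.0 * d
        alpha, info = overcompensation_fallback(R, tau)
        assert not info["exhausted"]
        assert info["scale"] == pytest.approx(0.7**4)
        produced = R @ alpha
        assert np.allclose(produced / np.linalg.norm(produced), d, atol=1e-8)

    def test_dead_direction_exhausts_after_ten_scalings(self):
        R = np.zeros((4, 9))
        R[0, 0] = 1.0            # no muscle can make torque on joints 1..3
        tau = np.array([0.0, 1.0, 0.0, 0.0])
        alpha, info = overcompensation_fallback(R, tau)
        assert info["exhausted"]
        assert info["attempts"] == 11   # original request + 10 scalings
        assert np.all(alpha == 0.0)


# ---------------------------------------------------------------------------
# linearization and MPC
# ---------------------------------------------------------------------------


class TestLinearization:
    def test_zoh_matches_matrix_exponential(self):
        rng = np.random.default_rng(5)
        Ac = rng.normal(0, 1, (6, 6))
        Bc = rng.normal(0, 1, (6, 3))
        dt = 0.05
        A, B, Phi = zoh_discretize(Ac, Bc, dt)
        aug = np.zeros((9, 9))
        aug[:6, :6] = Ac
        aug[:6, 6:] = Bc
        E = expm(aug * dt)
        assert np.abs(A - E[:6, :6]).max() < 1e-10
        assert np.abs(B - E[:6, 6:]).max() < 1e-10

    def test_dt_to_zero_limit(self):
        rng = np.random.default_rng(6)
        Ac = rng.normal(0, 1, (4, 4))
        Bc = rng.normal(0, 1, (4, 2))
        A, B, _ = zoh_discretize(Ac, Bc, 1e-9)
        assert np.abs(A - np.eye(4)).max() < 1e-7
        assert np.abs(B).max() < 1e-8

    def test_augmented_block_structure(self, subject):
        x = ArmState.at_rest(subject.equilibrium)
        lin = linearize_discretize(
            x, np.zeros(9), 0.02, subject.r_true, subject.parameters
        )
        Aa = lin.A_aug
        assert Aa.shape == (17, 17)
        assert np.allclose(Aa[:8, :8], lin.A)
        assert np.allclose(Aa[:8, 8:], lin.B)
        assert np.allclose(Aa[8:, :8], 0.0)
        assert np.allclose(Aa[8:, 8:], np.eye(9))
        assert np.allclose(lin.C_aug, np.hstack([lin.C, lin.D]))

    def test_prediction_tracks_nonlinear_flow(self, subject):
        """The ZOH drift reproduces the exact nonlinear flow to first order
        (the plant integrator itself is only O(dt) accurate, so the oracle
        here is a high-accuracy integration of the continuous dynamics)."""
        from scipy.integrate import solve_ivp

        from fesreach.arm_model import forward_dynamics

        p = subject.parameters
        model = subject.r_true
        x = ArmState.at_rest(subject.equilibrium)
        alpha = np.full(9, 0.2)
        dt = 0.02
        lin = linearize_discretize(x, alpha, dt, model, p)
        pred = lin.x_base + lin.drift

        def rhs(t, xv):
            st = ArmState.from_vector(xv)
            tau = model.torque_production_matrix(st.q) @ alpha
            return np.concatenate([st.omega, forward_dynamics(st, tau, p)])

        sol = solve_ivp(
            rhs, (0.0, dt), x.as_vector(), rtol=1e-10, atol=1e-12
        )
        truth = sol.y[:, -1]
        assert np.abs(pred - truth).max() < 1e-5


class TestMpc:
    def test_huge_lambda_freezes_activation(self, subject):
        x = ArmState.at_rest(subject.equilibrium)
        lin = linearize_discretize(
            x, np.full(9, 0.3), 0.02, subject.r_true, subject.parameters
        )
        cfg = MpcConfig(ny=4, nu=2, lam=1e6)
        ref = np.tile(subject.equilibrium + 0.1, (4, 1))
        alpha = mpc_step(lin, x, np.full(9, 0.3), ref, cfg)
        assert np.abs(alpha - 0.3).max() < 1e-6

    def test_single_step_equals_normal_equations(self, subject):
        x = ArmState.at_rest(subject.equilibrium)
        lin = linearize_discretize(
            x, np.full(9, 0.3), 0.02, subject.r_true, subject.parameters
        )
        cfg = MpcConfig(ny=1, nu=1, lam=0.001)
        ref = (subject.equilibrium + 0.02)[None, :]
        alpha = mpc_step(lin, x, np.full(9, 0.3), ref, cfg)
        G = lin.C @ lin.B
        h = ref[0] - lin.C @ (
            lin.x_base
            + lin.A @ (x.as_vector() - lin.x_base)
            + lin.drift
            - lin.B @ lin.alpha_base
        )
        expected = np.linalg.solve(
            G.T @ G + cfg.lam * np.eye(9),
            G.T @ h + cfg.lam * np.full(9, 0.3),
        )
        assert np.abs(alpha - expected).max() < 1e-8

    def test_activation_bounds_respected(self, subject):
        rng = np.random.default_rng(7)
        x = ArmState.at_rest(subject.equilibrium)
        lin = linearize_discretize(
            x, np.zeros(9), 0.02, subject.r_true, subject.parameters
        )
        cfg = MpcConfig(ny=4, nu=2, lam=1e-4)
        for _ in range(10):
            ref = np.tile(
                subject.equilibrium + rng.uniform(-0.5, 0.5, 4), (4, 1)
            )
            prev = rng.uniform(0, 1, 9)
            alpha = mpc_step(lin, x, prev, ref, cfg)
            assert np.all(alpha >= -1e-10)
            assert np.all(alpha <= 1 + 1e-10)

    def test_linear_plant_tracking_converges(self):
        """On an exactly linear stable plant with a reachable constant
        reference, the receding-horizon loop drives the output error to
        (near) zero geometrically."""
        # damped double integrator per joint with antagonist actuator
        # pairs (activations are non-negative, so each joint gets a
        # positive and a negative input column)
        Ac = np.zeros((8, 8))
        Ac[:4, 4:] = np.eye(4)
        Ac[4:, 4:] = -2.0 * np.eye(4)
        Bc = np.zeros((8, 9))
        Bc[4:, :4] = np.eye(4)
        Bc[4:, 4:8] = -np.eye(4)
        dt = 0.05
        A, B, _ = zoh_discretize(Ac, Bc, dt)
        C = np.zeros((4, 8))
        C[:, :4] = np.eye(4)
        ref = np.full(4, 0.3)
        x = np.zeros(8)
        alpha = np.zeros(9)
        cfg = MpcConfig(ny=5, nu=3, lam=1e-6)
        errs = []
        for _ in range(60):
            # drift for an exactly linear plant makes the model exact:
            # x1 = x_base + A dx + B dalpha + (A x_base - x_base + B a_base)
            lin = LinearizedDiscreteModel(
                A=A, B=B, C=C, D=np.zeros((4, 9)),
                drift=A @ x - x + B @ alpha, x_base=x, alpha_base=alpha,
            )
            st = ArmState.from_vector(x)
            alpha = mpc_step(lin, st, alpha, np.tile(ref, (cfg.ny, 1)), cfg)
            x = A @ x + B @ alpha
            errs.append(np.linalg.norm(C @ x - ref))
        assert errs[-1] < 2e-2
        assert errs[-1] < errs[5]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            MpcConfig(ny=2, nu=3)


# ---------------------------------------------------------------------------
# closed loop
# ---------------------------------------------------------------------------


class TestClosedLoop:
    def test_constant_equilibrium_reference_stays_put(self, subject):
        traj = quintic_direct_trajectory(
            subject.equilibrium, subject.equilibrium, 2.0, 30
        )
        for strategy in ("FB", "MPC"):
            out = run_closed_loop(
                strategy, subject.r_true, subject.r_true, traj,
                subject.parameters,
            )
            assert out.final_cartesian_error < 1e-9
            assert np.abs(out.activations).max() < 1e-6
            assert not out.stuck

    def test_fffb_requires_feedforward(self, subject):
        traj = quintic_direct_trajectory(
            subject.equilibrium, subject.equilibrium, 2.0, 10
        )
        with pytest.raises(ValueError):
            run_closed_loop(
                "FFFB", subject.r_true, subject.r_true, traj,
                subject.parameters,
            )

    def test_unknown_strategy_rejected(self, subject):
        traj = quintic_direct_trajectory(
            subject.equilibrium, subject.equilibrium, 2.0, 10
        )
        with pytest.raises(ValueError):
            run_closed_loop(
                "LQR", subject.r_true, subject.r_true, traj,
                subject.parameters,
            )

    def test_determinism(self, subject):
        qt = subject.equilibrium + np.array([0.2, -0.1, 0.0, 0.2])
        traj = quintic_direct_trajectory(subject.equilibrium, qt, 2.0, 25)
        outs = [
            run_closed_loop(
                "FB", subject.r_true, subject.r_true, traj, subject.parameters
            )
            for _ in range(2)
        ]
        assert np.array_equal(outs[0].states, outs[1].states)
        assert np.array_equal(outs[0].activations, outs[1].activations)

    def test_direct_path_into_weak_region_gets_stuck(self, subject):
        """Reaching far into the weak region with plain feedback engages the
        zero-activation fallback and ends far from the target."""
        qt = np.array([subject.q_min[0], subject.q_max[1], 0.0, subject.q_min[3]])
        traj = quintic_direct_trajectory(subject.equilibrium, qt, 2.0, 60)
        out = run_closed_loop(
            "FB", subject.r_true, subject.r_true, traj, subject.parameters
        )
        assert out.stuck
        assert out.final_cartesian_error > 0.05
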