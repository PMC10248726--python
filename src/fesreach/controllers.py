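"""Closed-loop control of FES-driven reaching along a reference trajectory.

Three strategies are provided, all operating on the muscle-capability model
the controller believes in (which may differ from the simulated plant):

* **FB** — joint-space PID maps tracking errors to desired torques; muscle
  redundancy is resolved by a minimum-norm quadratic program constrained to
  the achievable activation box.  When the requested torque is outside the
  achievable torque set, the request is repeatedly shrunk to 70% of itself
  (overcompensation fallback, at most 10 shrinkings) before giving up with
  zero activation — the mechanism behind "stuck" configurations.
* **FFFB** — the same feedback loop plus feedforward activations (from the
  planner, or from inverse dynamics for direct paths); the feedback QP keeps
  the total activation within bounds and falls back to feedforward alone.
* **MPC** — incremental model predictive control: the implicit dynamics are
  linearized about the current state, discretized by zero-order hold, and
  augmented with the previous activation so the decision variables are
  activation increments, adding integral action.  The box constraint on the
  cumulative activation is enforced inside the QP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy.linalg import expm
from scipy.optimize import linprog, minimize

from .arm_model import (
    N_DOF,
    N_MUSCLES,
    N_STATE,
    ArmParameters,
    ArmState,
    DegenerateStateError,
    NewtonConvergenceError,
    dynamics_jacobians,
    forward_dynamics,
    forward_kinematics,
    step_backward_euler,
)
from .muscle_capability import CapabilityModelBase

if TYPE_CHECKING:  # pragma: no cover
    from .planning import Trajectory

STRATEGIES = ("FB", "FFFB", "MPC")


@dataclass
class PidGains:
    """Joint-space PID gains (N m/rad, N m s/rad, N m/(rad s))."""

    kp: np.ndarray = field(default_factory=lambda: 10.0 * np.ones(N_DOF))
    kd: np.ndarray = field(default_factory=lambda: np.ones(N_DOF))
    ki: np.ndarray = field(default_factory=lambda: np.ones(N_DOF))
    integral_limit: float = 1.0   # rad s, anti-windup clamp

    def __post_init__(self):
        self.kp = np.broadcast_to(np.asarray(self.kp, float), (N_DOF,)).copy()
        self.kd = np.broadcast_to(np.asarray(self.kd, float), (N_DOF,)).copy()
        self.ki = np.broadcast_to(np.asarray(self.ki, float), (N_DOF,)).copy()
        if np.any(self.kp < 0) or np.any(self.kd < 0) or np.any(self.ki < 0):
            raise ValueError("PID gains must be non-negative")


@dataclass
class MpcConfig:
    """Incremental-MPC horizons and smoothness weight."""

    ny: int = 4           # prediction horizon, steps
    nu: int = 2           # control horizon, steps
    lam: float = 0.001    # weight on activation increments
    def __post_init__(self):
        if not (1 <= self.nu <= self.ny):
            raise ValueError("need 1 <= nu <= ny")


@dataclass
class LinearizedDiscreteModel:
    """ZOH-discretized linearization of the implicit arm dynamics.

    x_{k+1} ~ x_base + A (x_k - x_base) + B (alpha_k - alpha_base) + drift,
    y = C x.  The augmented form stacks the previous activation into the
    state so the control becomes the activation increment.
    """

    A: np.ndarray          # 8 x 8
    B: np.ndarray          # 8 x 9
    C: np.ndarray          # 4 x 8 (selects joint angles)
    D: np.ndarray          # 4 x 9 (zero)
    drift: np.ndarray      # 8, free-motion term over one step
    x_base: np.ndarray     # 8
    alpha_base: np.ndarray  # 9

    @property
    def A_aug(self) -> np.ndarray:
        top = np.hstack([self.A, self.B])
        bottom = np.hstack(
            [np.zeros((N_MUSCLES, N_STATE)), np.eye(N_MUSCLES)]
        )
        return np.vstack([top, bottom])

    @property
    def B_aug(self) -> np.ndarray:
        return np.vstack([self.B, np.eye(N_MUSCLES)])

    @property
    def C_aug(self) -> np.ndarray:
        return np.hstack([self.C, self.D])


@dataclass
class ReachOutcome:
    """Closed-loop result of one reach."""

    states: np.ndarray            # (n, 8)
    activations: np.ndarray       # (n, 9); last row zero
    reference: "Trajectory"
    final_joint_error: float      # rad, Euclidean over the 4 joints
    final_cartesian_error: float  # m, 3-D Euclidean wrist error
    stuck: bool                   # zero-activation fallback engaged
    strategy: str


# ---------------------------------------------------------------------------
# PID feedback
# ---------------------------------------------------------------------------


def pid_feedback_torque(
    x: ArmState,
    ref: ArmState,
    gains: PidGains,
    integral_state: np.ndarray,
    dt: float,
) -> np.ndarray:
    """tau = Kp e + Kd edot + Ki int(e); e = q_ref - q, edot = w_ref - w.

    ``integral_state`` (rad s) is updated in place by e*dt and clamped for
    anti-windup.
    """
    e = ref.q - x.q
    edot = ref.omega - x.omega
    tau = gains.kp * e + gains.kd * edot + gains.ki * integral_state
    integral_state += e * dt
    np.clip(
        integral_state, -gains.integral_limit, gains.integral_limit,
        out=integral_state,
    )
    return tau


# ---------------------------------------------------------------------------
# muscle-redundancy QP and overcompensation
# ---------------------------------------------------------------------------


def resolve_activations_qp(
    R: np.ndarray,
    tau_fb: np.ndarray,
    alpha_ff: Optional[np.ndarray] = None,
    tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Minimum-norm feedback activations: min ||a||^2, R a = tau, box bounds.

    The box is a + alpha_ff in [0, 1]^9 (alpha_ff = 0 without feedforward).
    Returns (activation, feasible); when the equality is unachievable inside
    the box the flag is False and the activation is zero.
    """
    R = np.asarray(R, dtype=float)
    tau_fb = np.asarray(tau_fb, dtype=float).reshape(R.shape[0])
    n = R.shape[1]
    if alpha_ff is None:
        alpha_ff = np.zeros(n)
    lo, hi = -np.asarray(alpha_ff, float), 1.0 - np.asarray(alpha_ff, float)

    # LP feasibility certificate (minimise equality slack over the box)
    m = R.shape[0]
    A_ub = np.block([[R, -np.eye(m)], [-R, -np.eye(m)]])
    b_ub = np.concatenate([tau_fb, -tau_fb])
    c = np.concatenate([np.zeros(n), np.ones(m)])
    lp = linprog(
        c, A_ub=A_ub, b_ub=b_ub,
        bounds=[(l, h) for l, h in zip(lo, hi)] + [(0, None)] * m,
        method="highs",
    )
    scale = max(1.0, float(np.linalg.norm(tau_fb)))
    if not lp.success or lp.fun > tol * scale:
        return np.zeros(n), False

    x0 = lp.x[:n]
    # reduce the equality system to independent rows (R may be rank
    # deficient, e.g. duplicated muscle columns), else SLSQP can stall
    U, S, _ = np.linalg.svd(R)
    rank = int(np.sum(S > 1e-10 * max(S[0], 1e-30)))
    A_eq = U[:, :rank].T @ R
    b_eq = U[:, :rank].T @ tau_fb
    res = minimize(
        lambda a: a @ a,
        x0,
        jac=lambda a: 2 * a,
        method="SLSQP",
        bounds=list(zip(lo, hi)),
        constraints=[{
            "type": "eq",
            "fun": lambda a: A_eq @ a - b_eq,
            "jac": lambda a: A_eq,
        }],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    alpha = np.clip(res.x, lo, hi)
    if np.linalg.norm(R @ alpha - tau_fb) > tol * scale:
        # SLSQP drifted; fall back to the LP vertex, which is feasible
        alpha = np.clip(x0, lo, hi)
        if np.linalg.norm(R @ alpha - tau_fb) > tol * scale:
            return np.zeros(n), False
    return alpha, True


def overcompensation_fallback(
    R: np.ndarray,
    tau_fb: np.ndarray,
    alpha_ff: Optional[np.ndarray] = None,
    shrink: float = 0.7,
    max_tries: int = 10,
) -> tuple[np.ndarray, dict]:
    """Shrink an unachievable torque request toward zero along its direction.

    Tries the full request, then ``shrink`` times the previous request up to
    ``max_tries`` scalings; the first achievable request is resolved by the
    minimum-norm QP.  If every scaling fails the feedback activation is zero
    (info["exhausted"] is True) — with feedforward present, the feedforward
    alone is passed through by the caller.
    """
    scale = 1.0
    for attempt in range(max_tries + 1):
        alpha, ok = resolve_activations_qp(R, scale * np.asarray(tau_fb), alpha_ff)
        if ok:
            return alpha, {"scale": scale, "attempts": attempt, "exhausted": False}
        scale *= shrink
    n = R.shape[1]
    return np.zeros(n), {
        "scale": 0.0, "attempts": max_tries + 1, "exhausted": True,
    }


# ---------------------------------------------------------------------------
# linearization and incremental MPC
# ---------------------------------------------------------------------------


def linearize_discretize(
    x: ArmState,
    alpha: np.ndarray,
    dt: float,
    model: CapabilityModelBase,
    p: ArmParameters,
) -> LinearizedDiscreteModel:
    """Linearize the implicit dynamics at (x, alpha) and ZOH-discretize.

    Continuous matrices: Ac = -(df/dxdot)^-1 df/dx, Bc = -(df/dxdot)^-1
    df/dalpha, evaluated at the state-consistent xdot.  The drift term is
    the zero-order-hold response to the free motion at the linearization
    point, so predictions started at x_base follow the nonlinear flow to
    first order.
    """
    alpha = np.asarray(alpha, dtype=float).reshape(N_MUSCLES)
    tau = model.torque_production_matrix(x.q) @ alpha
    omegadot = forward_dynamics(x, tau, p)
    xdot = np.concatenate([x.omega, omegadot])
    jac = dynamics_jacobians(x, xdot, alpha, model, p)
    try:
        inv = np.linalg.inv(jac.d_f_d_xdot)
    except np.linalg.LinAlgError as err:  # pragma: no cover
        raise DegenerateStateError("d f/d xdot is singular") from err
    Ac = -inv @ jac.d_f_d_x
    Bc = -inv @ jac.d_f_d_alpha
    A, B, Phi = zoh_discretize(Ac, Bc, dt)
    C = np.zeros((N_DOF, N_STATE))
    C[:, :N_DOF] = np.eye(N_DOF)
    return LinearizedDiscreteModel(
        A=A,
        B=B,
        C=C,
        D=np.zeros((N_DOF, N_MUSCLES)),
        drift=Phi @ xdot,
        x_base=x.as_vector(),
        alpha_base=alpha,
    )


def zoh_discretize(
    Ac: np.ndarray, Bc: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact zero-order-hold: A = e^(Ac dt), B = int_0^dt e^(Ac s) ds Bc.

    Also returns Phi = int_0^dt e^(Ac s) ds for affine drift terms.  Computed
    from one augmented matrix exponential.
    """
    nx = Ac.shape[0]
    nu = Bc.shape[1]
    aug = np.zeros((nx + nu + nx, nx + nu + nx))
    aug[:nx, :nx] = Ac
    aug[:nx, nx : nx + nu] = Bc
    aug[:nx, nx + nu :] = np.eye(nx)
    E = expm(aug * dt)
    return E[:nx, :nx], E[:nx, nx : nx + nu], E[:nx, nx + nu :]


def mpc_step(
    lin: LinearizedDiscreteModel,
    x: ArmState,
    alpha_prev: np.ndarray,
    reference_window: np.ndarray,
    cfg: MpcConfig,
) -> np.ndarray:
    """One receding-horizon step; returns the activation to apply now.

    Minimizes sum_{i=1..ny} ||q_ref_i - q_pred_i||^2
    + lam sum_{i=0..nu-1} ||dalpha_i||^2 with dalpha = 0 past the control
    horizon, subject to the cumulative activation staying in [0, 1]^9.  The
    decision variables are the cumulative activations of the nu controlled
    steps; the unconstrained solution is used whenever it respects the box,
    otherwise the box-QP is polished by a bounded quasi-Newton solve.
    """
    alpha_prev = np.asarray(alpha_prev, dtype=float).reshape(N_MUSCLES)
    ref = np.atleast_2d(np.asarray(reference_window, dtype=float))
    ny, nu = cfg.ny, cfg.nu
    if ref.shape[0] < ny:  # hold the last reference sample
        pad = np.tile(ref[-1], (ny - ref.shape[0], 1))
        ref = np.vstack([ref, pad])
    ref = ref[:ny]

    # affine prediction x_{i+1} = c_{i+1} + sum_j M_{i+1, j} u_j with
    # u_j the cumulative activation applied over step j (held past nu)
    A, B, drift = lin.A, lin.B, lin.drift
    x_dev = x.as_vector() - lin.x_base
    consts = np.empty((ny, N_STATE))
    coeffs = np.zeros((ny, nu, N_STATE, N_MUSCLES))
    c = x_dev
    Mpow = [np.eye(N_STATE)]
    for _ in range(ny):
        Mpow.append(A @ Mpow[-1])
    for i in range(ny):
        c = A @ c + drift - B @ lin.alpha_base
        consts[i] = lin.x_base + c
        for j in range(min(i + 1, nu)):
            steps = [s for s in range(i + 1) if min(s, nu - 1) == j]
            coeffs[i, j] = sum(Mpow[i - s] @ B for s in steps)

    Cmat = lin.C
    # stack the error system e = h - G u
    G = np.zeros((ny * N_DOF, nu * N_MUSCLES))
    h = np.zeros(ny * N_DOF)
    for i in range(ny):
        h[i * N_DOF : (i + 1) * N_DOF] = ref[i] - Cmat @ consts[i]
        for j in range(nu):
            G[i * N_DOF : (i + 1) * N_DOF, j * N_MUSCLES : (j + 1) * N_MUSCLES] = (
                Cmat @ coeffs[i, j]
            )
    # increment map dalpha = T u - t0
    T = np.eye(nu * N_MUSCLES)
    for j in range(1, nu):
        T[j * N_MUSCLES : (j + 1) * N_MUSCLES,
          (j - 1) * N_MUSCLES : j * N_MUSCLES] -= np.eye(N_MUSCLES)
    t0 = np.concatenate([alpha_prev, np.zeros((nu - 1) * N_MUSCLES)])

    sqrt_lam = np.sqrt(cfg.lam)
    A_ls = np.vstack([G, sqrt_lam * T])
    b_ls = np.concatenate([h, sqrt_lam * t0])
    u_free, *_ = np.linalg.lstsq(A_ls, b_ls, rcond=None)
    if np.all(u_free >= -1e-10) and np.all(u_free <= 1 + 1e-10):
        u = np.clip(u_free, 0.0, 1.0)
    else:
        H = A_ls.T @ A_ls
        g0 = -A_ls.T @ b_ls

        def fun(u):
            return 0.5 * u @ H @ u + g0 @ u

        def grad(u):
            return H @ u + g0

        res = minimize(
            fun,
            np.clip(u_free, 0.0, 1.0),
            jac=grad,
            method="L-BFGS-B",
            bounds=[(0.0, 1.0)] * (nu * N_MUSCLES),
            options={"maxiter": 500, "ftol": 1e-16, "gtol": 1e-12},
        )
        u = np.clip(res.x, 0.0, 1.0)
    return u[:N_MUSCLES]


# ---------------------------------------------------------------------------
# closed loop
# ---------------------------------------------------------------------------


def run_closed_loop(
    strategy: str,
    plant_model: CapabilityModelBase,
    controller_model: CapabilityModelBase,
    traj: "Trajectory",
    p: ArmParameters,
    alpha_ff: Optional[np.ndarray] = None,
    pid: Optional[PidGains] = None,
    mpc: Optional[MpcConfig] = None,
) -> ReachOutcome:
    """Drive the simulated plant along a reference trajectory.

    The plant steps with ``plant_model`` (the arm's true capabilities) while
    the controller only sees ``controller_model`` evaluated at the measured
    configuration — the ideal / uncertain / fatigued conditions differ only
    in how the two models relate.  FFFB requires ``alpha_ff`` (planner
    activations for planned paths, inverse-dynamics activations for direct
    paths).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    pid = pid or PidGains()
    mpc = mpc or MpcConfig()
    n = traj.n_nodes
    dt = traj.dt
    if strategy == "FFFB":
        if alpha_ff is None:
            raise ValueError("FFFB needs feedforward activations")
        alpha_ff = np.asarray(alpha_ff, dtype=float)
    states = np.empty((n, N_STATE))
    applied = np.zeros((n, N_MUSCLES))
    states[0] = traj.states[0]
    integral = np.zeros(N_DOF)
    alpha_prev = np.zeros(N_MUSCLES)
    stuck = False
    for k in range(n - 1):
        x = ArmState.from_vector(states[k])
        # PID error is against the simultaneous reference sample, so a
        # perfectly tracking plant sees zero feedback torque; MPC predicts
        # against the upcoming window
        ref = ArmState.from_vector(traj.states[k])
        if strategy in ("FB", "FFFB"):
            R = controller_model.torque_production_matrix(x.q)
            tau_fb = pid_feedback_torque(x, ref, pid, integral, dt)
            ff_k = alpha_ff[k] if strategy == "FFFB" else None
            alpha_fb, info = overcompensation_fallback(R, tau_fb, alpha_ff=ff_k)
            if info["exhausted"]:
                stuck = True
            alpha = alpha_fb if ff_k is None else np.clip(alpha_fb + ff_k, 0, 1)
        else:  # MPC
            lin = linearize_discretize(x, alpha_prev, dt, controller_model, p)
            window = traj.q[k + 1 : k + 1 + mpc.ny]
            alpha = mpc_step(lin, x, alpha_prev, window, mpc)
        applied[k] = alpha
        try:
            states[k + 1] = step_backward_euler(
                x, alpha, dt, plant_model, p
            ).as_vector()
        except NewtonConvergenceError as err:  # pragma: no cover
            raise RuntimeError(f"plant step {k} failed: {err}") from err
        alpha_prev = alpha
    q_target = traj.q[-1]
    jerr = float(np.linalg.norm(states[-1, :N_DOF] - q_target))
    cerr = float(
        np.linalg.norm(
            forward_kinematics(states[-1, :N_DOF], p)
            - forward_kinematics(q_target, p)
        )
    )
    return ReachOutcome(
        states=states,
        activations=applied,
        reference=traj,
        final_joint_error=jerr,
        final_cartesian_error=cerr,
        stuck=stuck,
        strategy=strategy,
    )
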