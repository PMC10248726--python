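"""Trajectory generation: minimum-jerk direct paths and collocation planning.

A reach is a 2 s motion from a start configuration at rest to a target
configuration at rest.  Two kinds of reference trajectories are produced:

* *direct-to-target*: a fifth-order (minimum-jerk) polynomial per joint with
  zero endpoint velocity and acceleration — the naive path a straight-line
  controller would follow;
* *planned*: the solution of a direct-collocation nonlinear program that
  respects the arm dynamics and the person-specific muscle capabilities.

The collocation NLP optimises all node states and activations jointly:

    minimize    mean(alpha^2) + gamma * mean((q - q_targ)^2)
    subject to  x_min <= x_k <= x_max          (workspace + velocity bounds)
                0 <= alpha <= 1
                f(x_{k+1}, (x_{k+1}-x_k)/dt, alpha_k) = 0   (dynamics defects)
                x_1 = (q_0, 0),  x_n = (q_targ, 0)

The defect uses the same backward-Euler discretisation as the simulator with
the activation held at the earlier node, so a feasible solution replays
exactly through the simulator — the principal end-to-end oracle.  Feasible
solutions are polished by forward re-integration of the optimized
activations, which drives the stored defects to solver precision while
moving the states only within the NLP tolerance.

With 100 nodes spanning 2 s the node spacing is duration/(n-1) ~ 0.0202 s
(the nominal 0.02 s step rounded); node counts for a given accuracy are
chosen by refining against a 200-node reference solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import Bounds, NonlinearConstraint, minimize
from scipy.sparse import coo_matrix, diags

from .arm_model import (
    N_DOF,
    N_MUSCLES,
    N_STATE,
    ArmParameters,
    ArmState,
    NewtonConvergenceError,
    _batch_rigid_jacobians,
    _rigid_residual_batch,
    capability_derivative_batch,
    forward_kinematics_batch,
    simulate,
)
from .muscle_capability import CapabilityModelBase

#: widening of the training joint range used for planner state bounds (rad)
WORKSPACE_MARGIN = np.deg2rad(11.0)
#: joint-velocity bound magnitude (rad/s)
VELOCITY_BOUND = 10.0
#: dynamics-defect violation accepted for a feasible solution (N m scale)
DEFECT_TOLERANCE = 1e-6
#: terminal joint error accepted after forward-replay polishing (rad)
TERMINAL_TOLERANCE = 1e-3


@dataclass
class TrajectoryOptimizationSpec:
    """Problem definition for one reach NLP."""

    x0: ArmState
    q_target: np.ndarray
    q_lower: np.ndarray
    q_upper: np.ndarray
    n_nodes: int = 100
    duration: float = 2.0
    velocity_bound: float = VELOCITY_BOUND
    gamma: float = 1.0            # rad^-2 weight on distance-to-target
    max_iterations: int = 1500
    retry_with_random_guess: bool = True
    retry_seed: int = 0

    def __post_init__(self):
        self.q_target = np.asarray(self.q_target, dtype=float).reshape(N_DOF)
        self.q_lower = np.asarray(self.q_lower, dtype=float).reshape(N_DOF)
        self.q_upper = np.asarray(self.q_upper, dtype=float).reshape(N_DOF)
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.duration <= 0 or self.gamma < 0:
            raise ValueError("bad duration or gamma")

    @property
    def dt(self) -> float:
        # n nodes span the full duration, so the step is duration/(n-1)
        return self.duration / (self.n_nodes - 1)

    @classmethod
    def for_reach(
        cls,
        model: CapabilityModelBase,
        x0: ArmState,
        q_target: np.ndarray,
        **kwargs,
    ) -> "TrajectoryOptimizationSpec":
        """Bounds from the model's training workspace widened by 11 deg."""
        return cls(
            x0=x0,
            q_target=q_target,
            q_lower=model.q_min - WORKSPACE_MARGIN,
            q_upper=model.q_max + WORKSPACE_MARGIN,
            **kwargs,
        )

    def replace(self, **kwargs) -> "TrajectoryOptimizationSpec":
        from dataclasses import replace as _replace

        return _replace(self, **kwargs)


@dataclass
class Trajectory:
    """Time-stamped states and activations with solver metadata."""

    times: np.ndarray            # (n,)
    states: np.ndarray           # (n, 8)
    activations: np.ndarray      # (n, 9); the last row is unused by defects
    status: str                  # feasible | infeasible | abandoned | direct
    objective: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        self.activations = np.asarray(self.activations, dtype=float)

    @property
    def n_nodes(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def q(self) -> np.ndarray:
        return self.states[:, :N_DOF]

    @property
    def omega(self) -> np.ndarray:
        return self.states[:, N_DOF:]

    def state(self, k: int) -> ArmState:
        return ArmState.from_vector(self.states[k])

    def wrist_path(self, p: ArmParameters) -> np.ndarray:
        return forward_kinematics_batch(self.q, p)

    # -- delimited-text round trip -----------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times}
        for k in range(N_DOF):
            cols[f"q{k}"] = self.states[:, k]
        for k in range(N_DOF):
            cols[f"w{k}"] = self.states[:, N_DOF + k]
        for k in range(N_MUSCLES):
            cols[f"a{k}"] = self.activations[:, k]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, status: str = "loaded") -> "Trajectory":
        df = pd.read_csv(path)
        states = df[[f"q{k}" for k in range(N_DOF)]
                    + [f"w{k}" for k in range(N_DOF)]].to_numpy()
        acts = df[[f"a{k}" for k in range(N_MUSCLES)]].to_numpy()
        return cls(df["time"].to_numpy(), states, acts, status=status)


# ---------------------------------------------------------------------------
# minimum-jerk direct path
# ---------------------------------------------------------------------------


def quintic_direct_trajectory(
    q0: np.ndarray,
    q_target: np.ndarray,
    duration: float = 2.0,
    n_nodes: int = 100,
) -> Trajectory:
    """Fifth-order per-joint path from rest to rest (minimum jerk).

    q(t) = q0 + (q_target - q0) (10 s^3 - 15 s^4 + 6 s^5), s = t/duration;
    velocity and acceleration vanish at both ends and activations are zero.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    q0 = np.asarray(q0, dtype=float).reshape(N_DOF)
    q_target = np.asarray(q_target, dtype=float).reshape(N_DOF)
    t = np.linspace(0.0, duration, n_nodes)
    s = t / duration
    shape = 10 * s**3 - 15 * s**4 + 6 * s**5
    dshape = (30 * s**2 - 60 * s**3 + 30 * s**4) / duration
    dq = q_target - q0
    states = np.empty((n_nodes, N_STATE))
    states[:, :N_DOF] = q0 + shape[:, None] * dq
    states[:, N_DOF:] = dshape[:, None] * dq
    return Trajectory(
        times=t,
        states=states,
        activations=np.zeros((n_nodes, N_MUSCLES)),
        status="direct",
    )


# ---------------------------------------------------------------------------
# collocation NLP
# ---------------------------------------------------------------------------


class _CollocationProblem:
    """Vectorised objective/constraints with a sparse analytic Jacobian.

    The boundary task constraints are eliminated: the first and last node
    states are fixed constants, so the decision vector is
    z = [interior states (n-2, 8) row-major, activations (n, 9)] and the
    interior-point solver never sees a degenerate equal-bound variable.
    Defect k couples nodes k and k+1 and activation row k.
    """

    def __init__(
        self,
        spec: TrajectoryOptimizationSpec,
        model: CapabilityModelBase,
        p: ArmParameters,
    ):
        self.spec = spec
        self.model = model
        self.p = p
        n = spec.n_nodes
        self.n = n
        self.nxi = (n - 2) * N_STATE
        self.nz = self.nxi + n * N_MUSCLES
        self.n_con = (n - 1) * N_STATE
        self.x_first = spec.x0.as_vector()
        self.x_last = np.concatenate([spec.q_target, np.zeros(N_DOF)])
        # row scaling: the rate-defect rows carry a 1/dt that would dominate
        # the torque-defect rows; scaling them by dt balances the Jacobian
        scale = np.ones(N_STATE)
        scale[:N_DOF] = self.spec.dt
        self.row_scale = np.tile(scale, n - 1)
        self._build_sparsity()

    # -- layout helpers -----------------------------------------------------
    def split(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Full (n, 8) state table (with pinned endpoints) and (n, 9) acts."""
        X = np.empty((self.n, N_STATE))
        X[0] = self.x_first
        X[-1] = self.x_last
        X[1:-1] = z[: self.nxi].reshape(self.n - 2, N_STATE)
        A = z[self.nxi :].reshape(self.n, N_MUSCLES)
        return X, A

    def pack(self, X: np.ndarray, A: np.ndarray) -> np.ndarray:
        return np.concatenate([X[1:-1].ravel(), A.ravel()])

    # -- objective ----------------------------------------------------------
    def objective(self, z: np.ndarray) -> float:
        X, A = self.split(z)
        dq = X[:, :N_DOF] - self.spec.q_target
        return float(
            np.sum(A * A) / A.size + self.spec.gamma * np.sum(dq * dq) / dq.size
        )

    def gradient(self, z: np.ndarray) -> np.ndarray:
        X, A = self.split(z)
        gX = np.zeros_like(X)
        gX[:, :N_DOF] = (
            2.0 * self.spec.gamma / (self.n * N_DOF)
            * (X[:, :N_DOF] - self.spec.q_target)
        )
        gA = 2.0 / A.size * A
        return self.pack(gX, gA)

    def hessian(self, z: np.ndarray):
        d = np.zeros(self.nz)
        hq = 2.0 * self.spec.gamma / (self.n * N_DOF)
        for k in range(N_DOF):
            d[k : self.nxi : N_STATE] = hq
        d[self.nxi :] = 2.0 / (self.n * N_MUSCLES)
        return diags(d)

    # -- defects ------------------------------------------------------------
    def defects(self, z: np.ndarray) -> np.ndarray:
        X, A = self.split(z)
        dt = self.spec.dt
        Qp, Wp = X[1:, :N_DOF], X[1:, N_DOF:]
        Qk, Wk = X[:-1, :N_DOF], X[:-1, N_DOF:]
        Ak = A[:-1]
        f1 = (Qp - Qk) / dt - Wp
        Rb = self.model.torque_production_matrix_batch(Qp)
        f2 = _rigid_residual_batch(Qp, Wp, (Wp - Wk) / dt, self.p)
        f2 = f2 - np.einsum("ncm,nm->nc", Rb, Ak)
        return np.concatenate([f1, f2], axis=1).ravel()

    def scaled_defects(self, z: np.ndarray) -> np.ndarray:
        return self.row_scale * self.defects(z)

    def scaled_defect_jacobian(self, z: np.ndarray):
        J = self.defect_jacobian(z).tocsr()
        return diags(self.row_scale) @ J

    def _build_sparsity(self) -> None:
        """Row/column indices of the defect Jacobian, endpoint columns cut.

        The data vector is generated densely per interval in a fixed order;
        entries whose column belongs to a pinned endpoint state are masked
        out once here and every evaluation reuses the mask.
        """
        n = self.n
        rows, cols = [], []

        def idx_state(k, j):  # -1 marks a pinned (eliminated) state column
            if k == 0 or k == n - 1:
                return -1
            return (k - 1) * N_STATE + j

        def idx_act(k, m):
            return self.nxi + k * N_MUSCLES + m

        for k in range(n - 1):
            r0 = k * N_STATE
            # f1 rows (4): q_k, q_{k+1}, w_{k+1} diagonals
            for j in range(N_DOF):
                rows += [r0 + j] * 3
                cols += [
                    idx_state(k, j),
                    idx_state(k + 1, j),
                    idx_state(k + 1, N_DOF + j),
                ]
            # f2 rows (4): dense in q_{k+1}, w_{k+1}, w_k, alpha_k
            for i in range(N_DOF):
                r = r0 + N_DOF + i
                for j in range(N_DOF):
                    rows += [r, r, r]
                    cols += [
                        idx_state(k + 1, j),
                        idx_state(k + 1, N_DOF + j),
                        idx_state(k, N_DOF + j),
                    ]
                for m in range(N_MUSCLES):
                    rows.append(r)
                    cols.append(idx_act(k, m))
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        self._jac_mask = cols >= 0
        self._jac_rows = rows[self._jac_mask]
        self._jac_cols = cols[self._jac_mask]

    def defect_jacobian(self, z: np.ndarray) -> coo_matrix:
        X, A = self.split(z)
        dt = self.spec.dt
        nm1 = self.n - 1
        Qp, Wp = X[1:, :N_DOF], X[1:, N_DOF:]
        Wk = X[:-1, N_DOF:]
        Ak = A[:-1]
        Wdot = (Wp - Wk) / dt
        df2_dq, df2_dw, M = _batch_rigid_jacobians(Qp, Wp, Wdot, self.p)
        dR_dq = capability_derivative_batch(self.model, Qp)    # (nm1, 4, 9, 4)
        Rb = self.model.torque_production_matrix_batch(Qp)
        Gq = df2_dq - np.einsum("ncmj,nm->ncj", dR_dq, Ak)
        Gw = df2_dw + M / dt
        Gwk = -M / dt

        data = np.empty(self._jac_mask.size)
        pos = 0
        per_f1 = 3 * N_DOF
        per_f2 = N_DOF * (3 * N_DOF + N_MUSCLES)
        for k in range(nm1):
            data[pos : pos + per_f1] = np.tile(
                [-1.0 / dt, 1.0 / dt, -1.0], N_DOF
            )
            pos += per_f1
            block = np.empty((N_DOF, 3 * N_DOF + N_MUSCLES))
            block[:, 0 : 3 * N_DOF : 3] = Gq[k]
            block[:, 1 : 3 * N_DOF : 3] = Gw[k]
            block[:, 2 : 3 * N_DOF : 3] = Gwk[k]
            block[:, 3 * N_DOF :] = -Rb[k]
            data[pos : pos + per_f2] = block.ravel()
            pos += per_f2
        return coo_matrix(
            (data[self._jac_mask], (self._jac_rows, self._jac_cols)),
            shape=(self.n_con, self.nz),
        )

    # -- bounds -------------------------------------------------------------
    def bounds(self) -> Bounds:
        n, spec = self.n, self.spec
        lb = np.empty(self.nz)
        ub = np.empty(self.nz)
        xl = np.concatenate(
            [spec.q_lower, -spec.velocity_bound * np.ones(N_DOF)]
        )
        xu = np.concatenate(
            [spec.q_upper, spec.velocity_bound * np.ones(N_DOF)]
        )
        lb[: self.nxi] = np.tile(xl, n - 2)
        ub[: self.nxi] = np.tile(xu, n - 2)
        lb[self.nxi :] = 0.0
        ub[self.nxi :] = 1.0
        return Bounds(lb, ub)

    def initial_guess(self, guess: Optional[Trajectory]) -> np.ndarray:
        if guess is None:
            guess = quintic_direct_trajectory(
                self.spec.x0.q, self.spec.q_target, self.spec.duration, self.n
            )
        X = guess.states.copy()
        A = guess.activations.copy()
        if X.shape[0] != self.n:  # resample a guess with a different grid
            t_new = np.linspace(0.0, self.spec.duration, self.n)
            t_old = np.linspace(0.0, self.spec.duration, X.shape[0])
            X = CubicSpline(t_old, X, axis=0)(t_new)
            A = CubicSpline(t_old, A, axis=0)(t_new)
        bounds = self.bounds()
        z = self.pack(X, np.clip(A, 0.0, 1.0))
        return np.clip(z, bounds.lb, bounds.ub)

    def random_guess(self, rng: np.random.Generator) -> np.ndarray:
        """Linear state interpolation with +-0.1 rad noise, alpha ~ U[0, 0.3]."""
        n, spec = self.n, self.spec
        lam = np.linspace(0.0, 1.0, n)[:, None]
        Q = (1 - lam) * spec.x0.q + lam * spec.q_target
        Q = Q + rng.uniform(-0.1, 0.1, size=Q.shape)
        W = np.zeros((n, N_DOF))
        X = np.hstack([Q, W])
        A = rng.uniform(0.0, 0.3, size=(n, N_MUSCLES))
        bounds = self.bounds()
        return np.clip(self.pack(X, A), bounds.lb, bounds.ub)


def solve_reach_nlp(
    spec: TrajectoryOptimizationSpec,
    model: CapabilityModelBase,
    p: ArmParameters,
    guess: Optional[Trajectory] = None,
    polish: bool = True,
) -> Trajectory:
    """Solve the reach NLP; retry once from a random guess, else abandon.

    A returned status of ``infeasible``/``abandoned`` means the solver found
    no acceptable trajectory — it does not prove that none exists.
    """
    prob = _CollocationProblem(spec, model, p)
    attempts = [prob.initial_guess(guess)]
    if spec.retry_with_random_guess:
        rng = np.random.default_rng(spec.retry_seed)
        attempts.append(prob.random_guess(rng))

    last = None
    for attempt, z0 in enumerate(attempts):
        traj = _solve_attempt(prob, z0, attempt, polish)
        if traj.status == "feasible":
            return traj
        last = traj
    last.status = "abandoned" if len(attempts) > 1 else last.status
    return last


class _StopOnPlateau:
    """Terminate a bounded number of iterations after reaching feasibility.

    The barrier method keeps polishing optimality long after the dynamics
    defects are satisfied, spending most of its budget on marginal
    objective gains.  A reach only needs defect feasibility plus a settled
    objective, so once the scaled violation first drops below ``viol_tol``
    the solver gets ``extra_iters`` more iterations and is then cut off.
    """

    def __init__(self, viol_tol: float = 3e-7, extra_iters: int = 150):
        self.viol_tol = viol_tol
        self.extra_iters = extra_iters
        self._feasible_at: int | None = None
        self._count = 0

    def __call__(self, xk, state) -> bool:
        self._count += 1
        if (
            self._feasible_at is None
            and float(state.constr_violation) <= self.viol_tol
        ):
            self._feasible_at = self._count
        return (
            self._feasible_at is not None
            and self._count >= self._feasible_at + self.extra_iters
            and float(state.constr_violation) <= self.viol_tol
        )


def _solve_attempt(
    prob: _CollocationProblem, z0: np.ndarray, attempt: int, polish: bool
) -> Trajectory:
    spec = prob.spec
    con = NonlinearConstraint(
        prob.scaled_defects,
        0.0,
        0.0,
        jac=prob.scaled_defect_jacobian,
        hess=lambda z, v: 0.0 * diags(np.ones(prob.nz)),
    )
    res = minimize(
        prob.objective,
        z0,
        jac=prob.gradient,
        hess=lambda z: prob.hessian(z),
        method="trust-constr",
        constraints=[con],
        bounds=prob.bounds(),
        callback=_StopOnPlateau(),
        options={
            "maxiter": spec.max_iterations,
            "gtol": 1e-7,
            "xtol": 1e-11,
            "verbose": 0,
        },
    )
    X, A = prob.split(res.x)
    times = np.linspace(0.0, spec.duration, spec.n_nodes)
    viol = float(np.abs(prob.defects(res.x)).max())
    diagnostics = {
        "solver_status": int(res.status),
        "solver_message": str(res.message),
        "iterations": int(res.niter),
        "constraint_violation": viol,
        "attempt": attempt,
    }
    status = "infeasible"
    states = X
    if viol <= DEFECT_TOLERANCE:
        if polish:
            try:
                sim = simulate(
                    ArmState.from_vector(X[0]), list(A[:-1]), spec.dt,
                    prob.model, prob.p,
                )
                X_sim = np.array([s.as_vector() for s in sim])
                term_err = float(
                    np.abs(X_sim[-1, :N_DOF] - spec.q_target).max()
                )
                diagnostics["terminal_error"] = term_err
                diagnostics["polish_shift"] = float(np.abs(X_sim - X).max())
                if term_err <= TERMINAL_TOLERANCE:
                    states = X_sim
                    status = "feasible"
            except NewtonConvergenceError as err:
                diagnostics["polish_failure"] = str(err)
        else:
            status = "feasible"
    return Trajectory(
        times=times,
        states=states,
        activations=A,
        status=status,
        objective=float(res.fun),
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# inverse dynamics along a given path
# ---------------------------------------------------------------------------


def inverse_dynamics_activations(
    traj: Trajectory,
    model: CapabilityModelBase,
    p: ArmParameters,
    tol: float = 1e-8,
) -> tuple[np.ndarray, bool]:
    """Feedforward activations driving the simulated arm along ``traj``.

    The joint-angle path is re-discretised with the simulator's backward
    Euler rule (velocities from backward differences, starting at rest), the
    required torque at each interval is computed from the inverse dynamics,
    and a minimum-norm activation in [0,1]^9 with R(q) alpha = tau is sought
    per interval.  If any interval admits no solution the reach is infeasible
    for open-loop muscle drive and all-zero activations are returned.
    """
    from .controllers import resolve_activations_qp

    n = traj.n_nodes
    dt = traj.dt
    Q = traj.q
    W = np.vstack([np.zeros(N_DOF), (Q[1:] - Q[:-1]) / dt])
    Wdot = (W[1:] - W[:-1]) / dt
    tau_req = _rigid_residual_batch(Q[1:], W[1:], Wdot, p)
    Rb = model.torque_production_matrix_batch(Q[1:])
    activations = np.zeros((n, N_MUSCLES))
    for k in range(n - 1):
        alpha, ok = resolve_activations_qp(Rb[k], tau_req[k], tol=tol)
        if not ok:
            return np.zeros((n, N_MUSCLES)), False
        activations[k] = alpha
    return activations, True


# ---------------------------------------------------------------------------
# node-count refinement
# ---------------------------------------------------------------------------


@dataclass
class NodeCountResult:
    count: int
    rms: float                  # wrist-path rms deviation from reference, m
    history: dict               # node count -> rms
    reference: Trajectory
    converged: bool = True      # loop terminated by meeting the tolerance

    def __int__(self) -> int:
        return self.count


def wrist_rms_deviation(
    traj: Trajectory, reference: Trajectory, p: ArmParameters
) -> float:
    """RMS 3-D wrist deviation after resampling onto the reference grid."""
    wr = reference.wrist_path(p)
    wt = CubicSpline(traj.times, traj.wrist_path(p), axis=0)(reference.times)
    return float(np.sqrt(np.mean(np.sum((wt - wr) ** 2, axis=1))))


def select_node_count(
    spec: TrajectoryOptimizationSpec,
    model: CapabilityModelBase,
    p: ArmParameters,
    reference_nodes: int = 200,
    tol: float = 1e-3,
    start: int = 10,
    step: int = 10,
    strict: bool = True,
) -> NodeCountResult:
    """Refine the node count against a dense reference solution.

    Solves the reach with ``reference_nodes`` nodes as ground truth, then
    increases the node count from ``start`` until the optimized wrist path
    deviates from the reference by at most ``tol`` (rms, metres, compared on
    the reference time grid).  All solves start from the planner's default
    quintic guess.  If no tried count meets the tolerance, ``strict=True``
    raises; otherwise the best (smallest-rms) count is returned with
    ``converged=False``.
    """
    ref = solve_reach_nlp(spec.replace(n_nodes=reference_nodes), model, p)
    if ref.status != "feasible":
        raise RuntimeError("reference solve failed; pick a feasible target")
    history: dict[int, float] = {}
    n = start
    # candidates stay strictly below the reference count: re-solving the
    # reference problem itself would compare a solution with itself
    while n < reference_nodes:
        traj = solve_reach_nlp(spec.replace(n_nodes=n), model, p)
        if traj.status == "feasible":
            rms = wrist_rms_deviation(traj, ref, p)
            history[n] = rms
            if rms <= tol:
                return NodeCountResult(n, rms, history, ref)
        else:
            history[n] = float("nan")
        n += step
    if strict:
        raise RuntimeError(
            f"no node count up to {reference_nodes} reached rms {tol}: {history}"
        )
    finite = {k: v for k, v in history.items() if np.isfinite(v)}
    best = min(finite, key=finite.get)
    return NodeCountResult(best, finite[best], history, ref, converged=False)
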