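"""Rigid-body dynamics of a two-link, four-DOF human arm in implicit form.

The arm is modelled as a humerus and a forearm driven by joint torques.  The
shoulder carries three rotations (plane of elevation, elevation, internal
rotation, an ISB-style Y-X-Y' mobile sequence) and the elbow one flexion
hinge.  Gravity is off by default: the intended use case is a person whose
arm rests in a mobile arm support assumed to compensate gravity perfectly.
For numerical stability the joints carry a small passive stiffness about an
equilibrium configuration and viscous damping.

The equations of motion are kept in the implicit state-space form

    f(x, xdot, tau) = [ qdot - omega ;
                        M(q) omegadot + C(q, omega) omega
                        + D omega + K (q - q_eq) + g_grav(q) - tau ] = 0

with x = (q, omega).  ``M`` is assembled from per-body point Jacobians,
``C omega`` from Christoffel symbols whose ingredient dM/dq is obtained by
complex-step differentiation of the (holomorphic) mass-matrix code, so both
terms are exact to machine precision without symbolic code generation.

Everything is vectorised over a batch of configurations because the
trajectory optimiser evaluates dynamics defects at every collocation node.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Sequence

import numpy as np
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .muscle_capability import MuscleCapabilityModel

N_DOF = 4
N_STATE = 2 * N_DOF
N_MUSCLES = 9

JOINT_NAMES = (
    "plane_of_elevation",
    "elevation",
    "shoulder_rotation",
    "elbow_flexion",
)

#: complex-step size for exact first derivatives of holomorphic code
_CSTEP = 1e-20
#: central-difference step (rad) for configuration derivatives of the
#: velocity-product and gravity terms
_FDSTEP = 1e-6
#: central-difference step (rad) for derivatives of the muscle capability
#: model R(q)
R_DERIVATIVE_STEP = 1e-4

_GRAVITY = 9.81  # m/s^2, along -y of the thorax frame


class NewtonConvergenceError(RuntimeError):
    """Backward-Euler Newton iteration failed to reach tolerance."""

    def __init__(self, message: str, residual_norm: float):
        super().__init__(message)
        self.residual_norm = residual_norm


class DegenerateStateError(RuntimeError):
    """The implicit dynamics are singular (d f/d xdot not invertible)."""


# ---------------------------------------------------------------------------
# parameters and state containers
# ---------------------------------------------------------------------------

# segment mass / centre-of-mass / radius-of-gyration fractions typical of
# anthropometric tables (upper arm, forearm); overridable per subject
_MASS_FRACTIONS = (0.028, 0.016)
_COM_FRACTIONS = (0.436, 0.430)
_ROG_TRANSVERSE = (0.322, 0.303)
_ROG_LONGITUDINAL = (0.13, 0.13)


@dataclass
class ArmParameters:
    """Geometry, inertia and passive-joint properties of the arm.

    Lengths in metres, masses in kilograms, inertias in kg m^2 about the
    segment centre of mass in the segment frame (the long axis is local -y),
    stiffness in N m/rad and damping in N m s/rad per degree of freedom.
    ``com_offsets`` are distances from the proximal joint along the segment.
    """

    humerus_length: float = 0.315
    forearm_length: float = 0.253
    segment_masses: np.ndarray = field(
        default_factory=lambda: np.array([1.736, 0.992])
    )
    com_offsets: np.ndarray = field(
        default_factory=lambda: np.array([0.436 * 0.315, 0.430 * 0.253])
    )
    segment_inertias: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 3))
    )
    joint_stiffness: np.ndarray = field(default_factory=lambda: np.ones(N_DOF))
    joint_damping: np.ndarray = field(default_factory=lambda: np.ones(N_DOF))
    equilibrium_config: np.ndarray = field(default_factory=lambda: np.zeros(N_DOF))
    gravity_enabled: bool = False

    def __post_init__(self):
        self.segment_masses = np.asarray(self.segment_masses, dtype=float)
        self.com_offsets = np.asarray(self.com_offsets, dtype=float)
        self.segment_inertias = np.asarray(self.segment_inertias, dtype=float)
        self.joint_stiffness = np.broadcast_to(
            np.asarray(self.joint_stiffness, dtype=float), (N_DOF,)
        ).copy()
        self.joint_damping = np.broadcast_to(
            np.asarray(self.joint_damping, dtype=float), (N_DOF,)
        ).copy()
        self.equilibrium_config = np.asarray(self.equilibrium_config, dtype=float)
        if np.all(self.segment_inertias == 0.0):
            self.segment_inertias = _default_inertias(
                self.segment_masses,
                np.array([self.humerus_length, self.forearm_length]),
            )
        if self.humerus_length <= 0 or self.forearm_length <= 0:
            raise ValueError("segment lengths must be positive")
        if np.any(self.segment_masses <= 0):
            raise ValueError("segment masses must be positive")
        if np.any(self.joint_stiffness < 0) or np.any(self.joint_damping < 0):
            raise ValueError("stiffness and damping must be non-negative")

    @classmethod
    def from_body_mass(
        cls,
        total_body_mass: float = 62.0,
        humerus_length: float = 0.315,
        forearm_length: float = 0.253,
        **kwargs,
    ) -> "ArmParameters":
        """Build parameters from total body mass via standard segment fractions."""
        lengths = np.array([humerus_length, forearm_length])
        masses = total_body_mass * np.asarray(_MASS_FRACTIONS)
        return cls(
            humerus_length=humerus_length,
            forearm_length=forearm_length,
            segment_masses=masses,
            com_offsets=np.asarray(_COM_FRACTIONS) * lengths,
            segment_inertias=_default_inertias(masses, lengths),
            **kwargs,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "humerus_length": float(self.humerus_length),
            "forearm_length": float(self.forearm_length),
            "segment_masses": self.segment_masses.tolist(),
            "com_offsets": self.com_offsets.tolist(),
            "segment_inertias": self.segment_inertias.tolist(),
            "joint_stiffness": self.joint_stiffness.tolist(),
            "joint_damping": self.joint_damping.tolist(),
            "equilibrium_config": self.equilibrium_config.tolist(),
            "gravity_enabled": bool(self.gravity_enabled),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArmParameters":
        d = dict(d)
        for key in (
            "segment_masses",
            "com_offsets",
            "segment_inertias",
            "joint_stiffness",
            "joint_damping",
            "equilibrium_config",
        ):
            if key in d:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "ArmParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_equilibrium(self, q_eq: np.ndarray) -> "ArmParameters":
        return replace(self, equilibrium_config=np.asarray(q_eq, dtype=float))


def _default_inertias(masses: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Principal segment inertias (x, y, z local; y = long axis)."""
    out = np.empty((2, 3))
    for i in range(2):
        it = masses[i] * (_ROG_TRANSVERSE[i] * lengths[i]) ** 2
        il = masses[i] * (_ROG_LONGITUDINAL[i] * lengths[i]) ** 2
        out[i] = (it, il, it)
    return out


@dataclass
class ArmState:
    """Joint angles ``q`` (rad) and angular velocities ``omega`` (rad/s)."""

    q: np.ndarray
    omega: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float).reshape(N_DOF)
        self.omega = np.asarray(self.omega, dtype=float).reshape(N_DOF)
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.omega))):
            raise ValueError("arm state must be finite")

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.q, self.omega])

    @classmethod
    def from_vector(cls, x: np.ndarray) -> "ArmState":
        x = np.asarray(x, dtype=float).reshape(N_STATE)
        return cls(q=x[:N_DOF], omega=x[N_DOF:])

    @classmethod
    def at_rest(cls, q: np.ndarray) -> "ArmState":
        return cls(q=np.asarray(q, dtype=float), omega=np.zeros(N_DOF))


@dataclass
class DynamicsJacobians:
    """Partial derivatives of the implicit dynamics residual."""

    d_f_d_x: np.ndarray       # 8 x 8
    d_f_d_xdot: np.ndarray    # 8 x 8
    d_f_d_alpha: np.ndarray   # 8 x 9


# ---------------------------------------------------------------------------
# kinematic chain (single place that fixes the rotation composition)
# ---------------------------------------------------------------------------
# Shoulder: R_h = Ry(q0) @ Rx(q1) @ Ry(q2)
#   q0 plane of elevation (about the thorax vertical y axis),
#   q1 elevation (about the rotated x axis),
#   q2 internal rotation (about the humeral long axis).
# Elbow: flexion hinge about the humeral local x axis, R_f = R_h @ Rx(q3).
# Segments point along local -y (the arm hangs down at q = 0).


def _ry(t: np.ndarray) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [np.stack([c, z, s], -1), np.stack([z, o, z], -1), np.stack([-s, z, c], -1)],
        -2,
    )


def _rx(t: np.ndarray) -> np.ndarray:
    c, s = np.cos(t), np.sin(t)
    z, o = np.zeros_like(c), np.ones_like(c)
    return np.stack(
        [np.stack([o, z, z], -1), np.stack([z, c, -s], -1), np.stack([z, s, c], -1)],
        -2,
    )


def _chain(Q: np.ndarray, p: ArmParameters) -> dict:
    """Batched kinematics; ``Q`` has shape (n, 4) (complex dtype allowed)."""
    q0, q1, q2, q3 = Q[..., 0], Q[..., 1], Q[..., 2], Q[..., 3]
    R1 = _ry(q0)
    R12 = R1 @ _rx(q1)
    Rh = R12 @ _ry(q2)
    Rf = Rh @ _rx(q3)
    down = np.array([0.0, -1.0, 0.0])
    u_h = Rh @ down            # humerus direction
    u_f = Rf @ down            # forearm direction
    p_elbow = p.humerus_length * u_h
    p_wrist = p_elbow + p.forearm_length * u_f
    zeros = np.zeros_like(q0)
    ones = np.ones_like(q0)
    z0 = np.stack([zeros, ones, zeros], -1)
    z1 = R1 @ np.array([1.0, 0.0, 0.0])
    z2 = R12 @ np.array([0.0, 1.0, 0.0])
    z3 = Rh @ np.array([1.0, 0.0, 0.0])
    return {
        "Rh": Rh,
        "Rf": Rf,
        "u_h": u_h,
        "u_f": u_f,
        "p_elbow": p_elbow,
        "p_wrist": p_wrist,
        "axes": np.stack([z0, z1, z2, z3], -2),  # (..., 4, 3)
    }


def forward_kinematics(q: np.ndarray, p: ArmParameters) -> np.ndarray:
    """Wrist position (3,) in metres relative to the shoulder."""
    out = _chain(np.asarray(q, dtype=float)[None, :], p)["p_wrist"][0]
    return out


def forward_kinematics_batch(Q: np.ndarray, p: ArmParameters) -> np.ndarray:
    """Wrist positions (n, 3) for configurations ``Q`` of shape (n, 4)."""
    return _chain(np.asarray(Q, dtype=float), p)["p_wrist"]


def arm_jacobian(q: np.ndarray, p: ArmParameters) -> np.ndarray:
    """3x4 Jacobian of the wrist position; J^T maps wrist force to torques."""
    return arm_jacobian_batch(np.asarray(q, dtype=float)[None, :], p)[0]


def arm_jacobian_batch(Q: np.ndarray, p: ArmParameters) -> np.ndarray:
    ch = _chain(np.asarray(Q), p)
    axes = ch["axes"]                       # (n, 4, 3)
    p_w = ch["p_wrist"][:, None, :]         # (n, 1, 3)
    origins = np.zeros_like(axes)
    origins[:, 3, :] = ch["p_elbow"]
    cols = np.cross(axes, p_w - origins)    # (n, 4, 3)
    return np.swapaxes(cols, -1, -2)        # (n, 3, 4)


# ---------------------------------------------------------------------------
# inertial terms
# ---------------------------------------------------------------------------


def _body_jacobians(Q: np.ndarray, p: ArmParameters) -> dict:
    ch = _chain(Q, p)
    axes = ch["axes"]                                    # (n, 4, 3)
    p_c1 = p.com_offsets[0] * ch["u_h"]                  # (n, 3)
    p_c2 = ch["p_elbow"] + p.com_offsets[1] * ch["u_f"]
    # humerus: joints 0..2 act, all at the shoulder (origin)
    jv1 = np.cross(axes, p_c1[:, None, :])
    jv1[:, 3, :] = 0.0
    jw1 = axes.copy()
    jw1[:, 3, :] = 0.0
    # forearm: all four joints act; elbow origin is p_elbow
    origins = np.zeros_like(axes)
    origins[:, 3, :] = ch["p_elbow"]
    jv2 = np.cross(axes, p_c2[:, None, :] - origins)
    jw2 = axes
    return {"ch": ch, "jv": (jv1, jv2), "jw": (jw1, jw2), "com": (p_c1, p_c2)}


def mass_matrix_batch(Q: np.ndarray, p: ArmParameters) -> np.ndarray:
    """Joint-space mass matrix M(q), batched: (n, 4, 4)."""
    bj = _body_jacobians(Q, p)
    rots = (bj["ch"]["Rh"], bj["ch"]["Rf"])
    M = np.zeros(Q.shape[:-1] + (N_DOF, N_DOF), dtype=Q.dtype)
    for i in range(2):
        jv, jw, R = bj["jv"][i], bj["jw"][i], rots[i]
        m = p.segment_masses[i]
        I_world = R @ (p.segment_inertias[i][:, None] * np.swapaxes(R, -1, -2))
        M = M + m * jv @ np.swapaxes(jv, -1, -2)
        M = M + jw @ I_world @ np.swapaxes(jw, -1, -2)
    return M


def mass_matrix(q: np.ndarray, p: ArmParameters) -> np.ndarray:
    return mass_matrix_batch(np.asarray(q, dtype=float)[None, :], p)[0]


def _dM_dq_batch(Q: np.ndarray, p: ArmParameters) -> np.ndarray:
    """dM/dq by complex step, shape (n, 4, 4, 4); last axis is d/dq_k."""
    n = Q.shape[0]
    out = np.empty((n, N_DOF, N_DOF, N_DOF))
    for k in range(N_DOF):
        Qc = Q.astype(complex)
        Qc[:, k] += 1j * _CSTEP
        out[..., k] = mass_matrix_batch(Qc, p).imag / _CSTEP
    return out


def coriolis_vector_batch(
    Q: np.ndarray, W: np.ndarray, p: ArmParameters, dM: np.ndarray | None = None
) -> np.ndarray:
    """C(q, omega) omega from Christoffel symbols, batched: (n, 4)."""
    if dM is None:
        dM = _dM_dq_batch(Q, p)
    # Gamma_ijk = 0.5 (dM_ij/dq_k + dM_ik/dq_j - dM_jk/dq_i)
    term1 = np.einsum("nijk,nj,nk->ni", dM, W, W)
    term2 = np.einsum("njki,nj,nk->ni", dM, W, W)
    return term1 - 0.5 * term2


def gravity_vector_batch(Q: np.ndarray, p: ArmParameters) -> np.ndarray:
    """Generalized gravity torque (n, 4); zero when gravity is disabled."""
    if not p.gravity_enabled:
        return np.zeros(Q.shape[:-1] + (N_DOF,), dtype=Q.dtype)
    bj = _body_jacobians(Q, p)
    g_force = np.array([0.0, -_GRAVITY, 0.0])
    out = np.zeros(Q.shape[:-1] + (N_DOF,), dtype=Q.dtype)
    for i in range(2):
        out = out - p.segment_masses[i] * bj["jv"][i] @ g_force
    return out


def _rigid_residual_batch(
    Q: np.ndarray,
    W: np.ndarray,
    Wdot: np.ndarray,
    p: ArmParameters,
    dM: np.ndarray | None = None,
) -> np.ndarray:
    """M wdot + C w + D w + K (q - q_eq) + g_grav(q), batched (n, 4)."""
    M = mass_matrix_batch(Q, p)
    cor = coriolis_vector_batch(Q, W, p, dM=dM)
    passive = p.joint_damping * W + p.joint_stiffness * (Q - p.equilibrium_config)
    return np.einsum("nij,nj->ni", M, Wdot) + cor + passive + gravity_vector_batch(Q, p)


def implicit_dynamics(
    x: ArmState, xdot: np.ndarray, tau: np.ndarray, p: ArmParameters
) -> np.ndarray:
    """Residual f(x, xdot, tau) of the implicit equations of motion (8,).

    ``xdot`` stacks (qdot, omegadot).  The residual vanishes exactly when the
    pair satisfies the equations of motion under joint torque ``tau``.
    """
    xdot = np.asarray(xdot, dtype=float).reshape(N_STATE)
    tau = np.asarray(tau, dtype=float).reshape(N_DOF)
    f1 = xdot[:N_DOF] - x.omega
    f2 = (
        _rigid_residual_batch(
            x.q[None, :], x.omega[None, :], xdot[None, N_DOF:], p
        )[0]
        - tau
    )
    return np.concatenate([f1, f2])


def forward_dynamics(
    x: ArmState, tau: np.ndarray, p: ArmParameters
) -> np.ndarray:
    """Explicit accelerations: solve M omegadot = tau - C w - passive - grav."""
    M = mass_matrix(x.q, p)
    rhs = np.asarray(tau, dtype=float) - _rigid_residual_batch(
        x.q[None, :], x.omega[None, :], np.zeros((1, N_DOF)), p
    )[0]
    return np.linalg.solve(M, rhs)


# ---------------------------------------------------------------------------
# Jacobians of the implicit residual (muscle-driven form, Eq-structure
# f = [qdot - w; M wdot + C w + passive + grav - R(q) alpha])
# ---------------------------------------------------------------------------


def _batch_rigid_jacobians(
    Q: np.ndarray, W: np.ndarray, Wdot: np.ndarray, p: ArmParameters
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(df2/dq, df2/dw, M) for the rigid part, each batched.

    df2/dw is exact (Christoffel contraction + damping); df2/dq uses central
    differences of the machine-precision rigid residual.
    """
    n = Q.shape[0]
    dM = _dM_dq_batch(Q, p)
    M = mass_matrix_batch(Q, p)
    # d(Cw)/dw_l = sum_k (Gamma_ilk + Gamma_ikl) w_k, from dM/dq
    g1 = np.einsum("nijk,nk->nij", dM, W)          # dM_ij/dq_k w_k
    g2 = np.einsum("nikj,nk->nij", dM, W)          # dM_ik/dq_j w_k -> (i, j)
    g3 = np.einsum("njki,nk->nij", dM, W)          # dM_jk/dq_i as (i, l=j)
    dcor_dw = g1 + g2 - g3
    df2_dw = dcor_dw + np.eye(N_DOF) * p.joint_damping
    # configuration derivative by central differences
    df2_dq = np.empty((n, N_DOF, N_DOF))
    for k in range(N_DOF):
        dq = np.zeros(N_DOF)
        dq[k] = _FDSTEP
        hi = _rigid_residual_batch(Q + dq, W, Wdot, p)
        lo = _rigid_residual_batch(Q - dq, W, Wdot, p)
        df2_dq[..., k] = (hi - lo) / (2 * _FDSTEP)
    return df2_dq, df2_dw, M


def dynamics_jacobians(
    x: ArmState,
    xdot: np.ndarray,
    alpha: np.ndarray,
    model: "MuscleCapabilityModel",
    p: ArmParameters,
) -> DynamicsJacobians:
    """Jacobians of f(x, xdot, alpha) = 0 with the muscle term -R(q) alpha."""
    xdot = np.asarray(xdot, dtype=float).reshape(N_STATE)
    alpha = np.asarray(alpha, dtype=float).reshape(N_MUSCLES)
    Q = x.q[None, :]
    df2_dq, df2_dw, Mb = _batch_rigid_jacobians(
        Q, x.omega[None, :], xdot[None, N_DOF:], p
    )
    R = model.torque_production_matrix(x.q)
    dR_dq = capability_derivative(model, x.q)        # (4, 9, 4)
    d_f_d_x = np.zeros((N_STATE, N_STATE))
    d_f_d_x[:N_DOF, N_DOF:] = -np.eye(N_DOF)
    d_f_d_x[N_DOF:, :N_DOF] = df2_dq[0] - np.einsum("cmk,m->ck", dR_dq, alpha)
    d_f_d_x[N_DOF:, N_DOF:] = df2_dw[0]
    d_f_d_xdot = np.zeros((N_STATE, N_STATE))
    d_f_d_xdot[:N_DOF, :N_DOF] = np.eye(N_DOF)
    d_f_d_xdot[N_DOF:, N_DOF:] = Mb[0]
    if not np.all(np.isfinite(Mb[0])) or np.linalg.cond(Mb[0]) > 1e12:
        raise DegenerateStateError("mass matrix is singular at this state")
    d_f_d_alpha = np.zeros((N_STATE, N_MUSCLES))
    d_f_d_alpha[N_DOF:, :] = -R
    return DynamicsJacobians(d_f_d_x, d_f_d_xdot, d_f_d_alpha)


def capability_derivative(
    model: "MuscleCapabilityModel", q: np.ndarray, step: float = R_DERIVATIVE_STEP
) -> np.ndarray:
    """dR/dq by central differences: (4, 9, 4), last axis d/dq_k."""
    return capability_derivative_batch(model, np.asarray(q, dtype=float)[None, :], step)[0]


def capability_derivative_batch(
    model: "MuscleCapabilityModel", Q: np.ndarray, step: float = R_DERIVATIVE_STEP
) -> np.ndarray:
    n = Q.shape[0]
    out = np.empty((n, N_DOF, N_MUSCLES, N_DOF))
    for k in range(N_DOF):
        dq = np.zeros(N_DOF)
        dq[k] = step
        out[..., k] = (
            model.torque_production_matrix_batch(Q + dq)
            - model.torque_production_matrix_batch(Q - dq)
        ) / (2 * step)
    return out


# ---------------------------------------------------------------------------
# backward-Euler time stepping
# ---------------------------------------------------------------------------


def step_backward_euler(
    x_k: ArmState,
    alpha_k: np.ndarray,
    dt: float,
    model: "MuscleCapabilityModel",
    p: ArmParameters,
    tol: float = 1e-10,
    max_iter: int = 50,
    max_step: float = 0.5,
) -> ArmState:
    """One implicit Euler step with the activation held over the interval.

    Solves f(x_{k+1}, (x_{k+1} - x_k)/dt, alpha_k) = 0 by a damped Newton
    iteration with the analytic residual Jacobian.  Newton updates are
    capped at ``max_step`` (inf-norm): at large time steps the implicit
    equation can admit several roots where the capability field is steep,
    and the cap keeps the iteration in the basin of the root adjacent to
    the previous state — the one the continuous dynamics actually visit.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    alpha_k = np.asarray(alpha_k, dtype=float).reshape(N_MUSCLES)
    xk_vec = x_k.as_vector()
    x = xk_vec.copy()

    def residual(xv: np.ndarray) -> np.ndarray:
        st = ArmState.from_vector(xv)
        tau = model.torque_production_matrix(st.q) @ alpha_k
        return implicit_dynamics(st, (xv - xk_vec) / dt, tau, p)

    r = residual(x)
    norm = float(np.linalg.norm(r))
    for _ in range(max_iter):
        if norm <= tol:
            return ArmState.from_vector(x)
        st = ArmState.from_vector(x)
        jac = dynamics_jacobians(st, (x - xk_vec) / dt, alpha_k, model, p)
        J = jac.d_f_d_x + jac.d_f_d_xdot / dt
        delta = np.linalg.solve(J, -r)
        step_norm = float(np.abs(delta).max())
        if step_norm > max_step:
            delta *= max_step / step_norm
        lam = 1.0
        for _ in range(30):
            r_new = residual(x + lam * delta)
            norm_new = float(np.linalg.norm(r_new))
            if norm_new < norm or norm_new <= tol:
                break
            lam *= 0.5
        x = x + lam * delta
        r, norm = r_new, norm_new
    if norm <= tol:
        return ArmState.from_vector(x)
    raise NewtonConvergenceError(
        f"backward-Euler Newton did not converge (residual {norm:.3e})", norm
    )


def simulate(
    x0: ArmState,
    activations: Sequence[np.ndarray],
    dt: float,
    model: "MuscleCapabilityModel",
    p: ArmParameters,
    tol: float = 1e-10,
) -> list[ArmState]:
    """Roll the arm forward; returns len(activations) + 1 states, first x0."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    states = [x0]
    for k, alpha in enumerate(activations):
        try:
            states.append(
                step_backward_euler(states[-1], alpha, dt, model, p, tol=tol)
            )
        except NewtonConvergenceError as err:
            raise NewtonConvergenceError(
                f"simulation failed at step {k}: {err}", err.residual_norm
            ) from err
    return states
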