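"""Configuration-dependent muscle torque-production modelling.

Stimulating a muscle group at its maximum produces joint torques that depend
on the arm configuration.  Assuming torques from simultaneously stimulated
groups combine linearly, the map from a 9-vector of activations (fractions
of maximum stimulation) to the 4 joint torques is

    tau = R(q) alpha,        R(q) in R^{4x9},

where column i of R is the torque produced by muscle group i at full
activation.  R(q) is learned from a capability-measurement experiment:
at a grid of configurations the wrist force (mapped to joint torques through
the arm-Jacobian transpose) is recorded with no stimulation (baseline) and
with each group stimulated alone, several repetitions each.

Each torque component of each muscle group (and of the baseline) is fitted
with a semiparametric Gaussian-process regression: a parametric mean that is
linear in [1, q, sin q, cos q] plus a zero-mean GP residual with an
anisotropic squared-exponential kernel and a white-noise term, hyperparameters
by marginal-likelihood maximisation.  The predicted muscle contribution is
the stimulated prediction minus the baseline prediction.  The posterior
variance drives the "uncertain model" variants used for robustness studies;
the "fatigued model" scales R by a constant factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .arm_model import N_DOF, N_MUSCLES, ArmParameters, arm_jacobian_batch

_N_FEATURES = 1 + 3 * N_DOF  # [1, q, sin q, cos q]


def _features(Q: np.ndarray) -> np.ndarray:
    Q = np.atleast_2d(Q)
    return np.hstack([np.ones((Q.shape[0], 1)), Q, np.sin(Q), np.cos(Q)])


def validate_activation(alpha: np.ndarray) -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float).reshape(N_MUSCLES)
    if np.any(alpha < -1e-12) or np.any(alpha > 1 + 1e-12):
        raise ValueError("activations must lie in [0, 1]")
    return np.clip(alpha, 0.0, 1.0)


# ---------------------------------------------------------------------------
# capability dataset
# ---------------------------------------------------------------------------


@dataclass
class CapabilityDataset:
    """Paired baseline / per-muscle stimulated torque samples on a config grid.

    ``configurations``: (n_cfg, 4) rad; ``baseline``: (n_cfg, reps, 4) N m;
    ``stimulated``: (n_cfg, 9, reps, 4) N m.  Every stimulated sample has a
    paired baseline at the same configuration.
    """

    configurations: np.ndarray
    baseline: np.ndarray
    stimulated: np.ndarray

    def __post_init__(self):
        self.configurations = np.asarray(self.configurations, dtype=float)
        self.baseline = np.asarray(self.baseline, dtype=float)
        self.stimulated = np.asarray(self.stimulated, dtype=float)
        n_cfg = self.configurations.shape[0]
        if self.configurations.shape != (n_cfg, N_DOF):
            raise ValueError("configurations must be (n_cfg, 4)")
        reps = self.baseline.shape[1]
        if self.baseline.shape != (n_cfg, reps, N_DOF):
            raise ValueError("baseline must be (n_cfg, reps, 4)")
        if self.stimulated.shape != (n_cfg, N_MUSCLES, reps, N_DOF):
            raise ValueError("stimulated must be (n_cfg, 9, reps, 4)")

    @property
    def n_configurations(self) -> int:
        return self.configurations.shape[0]

    @property
    def repetitions(self) -> int:
        return self.baseline.shape[1]

    # -- delimited-text round trip -----------------------------------------
    # columns: q0..q3 (rad), muscle (0 = baseline, 1..9), repetition,
    # tau0..tau3 (N m)
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, q in enumerate(self.configurations):
            for r in range(self.repetitions):
                rows.append([*q, 0, r, *self.baseline[i, r]])
                for m in range(N_MUSCLES):
                    rows.append([*q, m + 1, r, *self.stimulated[i, m, r]])
        cols = [f"q{k}" for k in range(N_DOF)] + ["muscle", "repetition"] + [
            f"tau{k}" for k in range(N_DOF)
        ]
        df = pd.DataFrame(rows, columns=cols)
        df["muscle"] = df["muscle"].astype(int)
        df["repetition"] = df["repetition"].astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CapabilityDataset":
        qcols = [f"q{k}" for k in range(N_DOF)]
        tcols = [f"tau{k}" for k in range(N_DOF)]
        configs = df[qcols].drop_duplicates().to_numpy()
        reps = int(df["repetition"].max()) + 1
        n_cfg = configs.shape[0]
        baseline = np.zeros((n_cfg, reps, N_DOF))
        stim = np.zeros((n_cfg, N_MUSCLES, reps, N_DOF))
        for i, q in enumerate(configs):
            sel = df[np.all(np.isclose(df[qcols].to_numpy(), q), axis=1)]
            for _, row in sel.iterrows():
                m, r = int(row["muscle"]), int(row["repetition"])
                tau = row[tcols].to_numpy(dtype=float)
                if m == 0:
                    baseline[i, r] = tau
                else:
                    stim[i, m - 1, r] = tau
        return cls(configs, baseline, stim)

    @classmethod
    def from_csv(cls, path) -> "CapabilityDataset":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def from_force_csv(cls, path, params: ArmParameters) -> "CapabilityDataset":
        return cls.from_force_frame(pd.read_csv(path), params)

    @classmethod
    def from_force_frame(
        cls, df: pd.DataFrame, params: ArmParameters
    ) -> "CapabilityDataset":
        """Build from wrist-force records (fx, fy, fz in N) via tau = J^T F."""
        qcols = [f"q{k}" for k in range(N_DOF)]
        Q = df[qcols].to_numpy(dtype=float)
        F = df[["fx", "fy", "fz"]].to_numpy(dtype=float)
        J = arm_jacobian_batch(Q, params)               # (n, 3, 4)
        tau = np.einsum("nck,nc->nk", J, F)
        out = df[qcols + ["muscle", "repetition"]].copy()
        for k in range(N_DOF):
            out[f"tau{k}"] = tau[:, k]
        return cls.from_frame(out)


# ---------------------------------------------------------------------------
# semiparametric GPR on a single scalar output
# ---------------------------------------------------------------------------


class _SemiparametricGPR:
    """Linear trig-feature mean + GP residual for one torque component."""

    def __init__(self, n_restarts: int = 5, seed: int = 0):
        self.n_restarts = n_restarts
        self.seed = seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_SemiparametricGPR":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        Phi = _features(X)
        self.beta_, *_ = np.linalg.lstsq(Phi, y, rcond=None)
        resid = y - Phi @ self.beta_
        span = np.maximum(X.max(axis=0) - X.min(axis=0), 1e-3)
        kernel = ConstantKernel(
            max(resid.var(), 1e-8), (1e-8, 1e4)
        ) * RBF(0.5 * span, [(s * 1e-2, s * 1e2) for s in span]) + WhiteKernel(
            1e-6, (1e-12, 1e2)
        )
        self.gp_ = GaussianProcessRegressor(
            kernel=kernel,
            n_restarts_optimizer=self.n_restarts,
            normalize_y=False,
            random_state=self.seed,
        )
        self.gp_.fit(X, resid)
        k = self.gp_.kernel_
        self.X_train_ = X
        self.const_ = float(k.k1.k1.constant_value)
        self.length_scale_ = np.atleast_1d(np.asarray(k.k1.k2.length_scale, float))
        if self.length_scale_.size == 1:
            self.length_scale_ = np.full(N_DOF, self.length_scale_[0])
        self.noise_ = float(k.k2.noise_level)
        self.alpha_ = self.gp_.alpha_.ravel()
        self.y_train_ = y
        return self

    def predict(self, Q: np.ndarray, return_std: bool = False):
        Q = np.atleast_2d(Q)
        mean_param = _features(Q) @ self.beta_
        if return_std:
            resid_mean, std = self.gp_.predict(Q, return_std=True)
            return mean_param + resid_mean, std
        d = (Q[:, None, :] - self.X_train_[None, :, :]) / self.length_scale_
        K = self.const_ * np.exp(-0.5 * np.einsum("qnk->qn", d * d))
        return mean_param + K @ self.alpha_

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "beta": self.beta_.tolist(),
            "X_train": self.X_train_.tolist(),
            "y_train": self.y_train_.tolist(),
            "const": self.const_,
            "length_scale": self.length_scale_.tolist(),
            "noise": self.noise_,
            "alpha": self.alpha_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_SemiparametricGPR":
        self = cls()
        self.beta_ = np.asarray(d["beta"], float)
        self.X_train_ = np.asarray(d["X_train"], float)
        self.y_train_ = np.asarray(d["y_train"], float)
        self.const_ = float(d["const"])
        self.length_scale_ = np.asarray(d["length_scale"], float)
        self.noise_ = float(d["noise"])
        self.alpha_ = np.asarray(d["alpha"], float)
        kernel = ConstantKernel(self.const_, "fixed") * RBF(
            self.length_scale_, "fixed"
        ) + WhiteKernel(self.noise_, "fixed")
        self.gp_ = GaussianProcessRegressor(kernel=kernel, optimizer=None)
        resid = self.y_train_ - _features(self.X_train_) @ self.beta_
        self.gp_.fit(self.X_train_, resid)
        return self


# ---------------------------------------------------------------------------
# capability models
# ---------------------------------------------------------------------------


class CapabilityModelBase:
    """Minimal interface shared by fitted, scaled and analytic models."""

    q_min: np.ndarray
    q_max: np.ndarray

    def torque_production_matrix(self, q: np.ndarray) -> np.ndarray:
        return self.torque_production_matrix_batch(
            np.asarray(q, dtype=float)[None, :]
        )[0]

    def torque_production_matrix_batch(self, Q: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def muscle_torque(self, q: np.ndarray, alpha: np.ndarray) -> np.ndarray:
        alpha = validate_activation(alpha)
        return self.torque_production_matrix(q) @ alpha

    def in_workspace(self, q: np.ndarray) -> bool:
        q = np.asarray(q, dtype=float)
        return bool(np.all(q >= self.q_min - 1e-12) and np.all(q <= self.q_max + 1e-12))


class MuscleCapabilityModel(CapabilityModelBase):
    """Fitted semiparametric-GPR predictor of R(q) with predictive variance.

    Column i of R(q) is the predicted torque of muscle group i at full
    activation: stimulated prediction minus baseline prediction.
    """

    def __init__(
        self,
        muscle_regressors: list,   # [9][4] _SemiparametricGPR
        baseline_regressors: list,  # [4]
        q_min: np.ndarray,
        q_max: np.ndarray,
    ):
        self.muscle_regressors = muscle_regressors
        self.baseline_regressors = baseline_regressors
        self.q_min = np.asarray(q_min, dtype=float)
        self.q_max = np.asarray(q_max, dtype=float)
        self._compile()

    def _compile(self) -> None:
        """Stack regressor parameters for fast batched prediction."""
        regs = [
            self.muscle_regressors[m][c]
            for m in range(N_MUSCLES)
            for c in range(N_DOF)
        ] + list(self.baseline_regressors)
        self._X = regs[0].X_train_
        self._invl2 = np.stack([1.0 / r.length_scale_**2 for r in regs])
        self._const = np.array([r.const_ for r in regs])
        self._alpha = np.stack([r.alpha_ for r in regs])
        self._beta = np.stack([r.beta_ for r in regs])

    def torque_production_matrix_batch(self, Q: np.ndarray) -> np.ndarray:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        diff = Q[:, None, :] - self._X[None, :, :]           # (nq, N, 4)
        d2 = np.einsum("qnk,rk->rqn", diff * diff, self._invl2)
        K = self._const[:, None, None] * np.exp(-0.5 * d2)   # (R, nq, N)
        mean = np.einsum("rqn,rn->rq", K, self._alpha) + self._beta @ _features(Q).T
        stim = mean[: N_MUSCLES * N_DOF].reshape(N_MUSCLES, N_DOF, Q.shape[0])
        base = mean[N_MUSCLES * N_DOF :]                      # (4, nq)
        R = stim - base[None, :, :]                           # (9, 4, nq)
        return np.transpose(R, (2, 1, 0))                     # (nq, 4, 9)

    def predictive_std(self, q: np.ndarray) -> np.ndarray:
        """Std of each entry of R(q): (4, 9); muscle and baseline variances add."""
        q = np.asarray(q, dtype=float)[None, :]
        base_var = np.array(
            [self.baseline_regressors[c].predict(q, return_std=True)[1][0] ** 2
             for c in range(N_DOF)]
        )
        out = np.empty((N_DOF, N_MUSCLES))
        for m in range(N_MUSCLES):
            for c in range(N_DOF):
                _, s = self.muscle_regressors[m][c].predict(q, return_std=True)
                out[c, m] = np.sqrt(s[0] ** 2 + base_var[c])
        return out

    # -- serialization ------------------------------------------------------
    def save(self, path) -> None:
        doc = {
            "q_min": self.q_min.tolist(),
            "q_max": self.q_max.tolist(),
            "muscles": [
                [self.muscle_regressors[m][c].to_dict() for c in range(N_DOF)]
                for m in range(N_MUSCLES)
            ],
            "baseline": [r.to_dict() for r in self.baseline_regressors],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "MuscleCapabilityModel":
        with open(path) as fh:
            doc = json.load(fh)
        muscles = [
            [_SemiparametricGPR.from_dict(d) for d in row] for row in doc["muscles"]
        ]
        baseline = [_SemiparametricGPR.from_dict(d) for d in doc["baseline"]]
        return cls(muscles, baseline, doc["q_min"], doc["q_max"])


class ScaledCapabilityModel(CapabilityModelBase):
    """Capability model with every torque scaled by a constant factor.

    Emulates uniform fatigue: magnitudes shrink, joint-space directions of
    every muscle column are preserved.
    """

    def __init__(self, base: CapabilityModelBase, factor: float):
        if not (0.0 < factor <= 1.0):
            raise ValueError("fatigue factor must be in (0, 1]")
        self.base = base
        self.factor = float(factor)
        self.q_min = base.q_min
        self.q_max = base.q_max

    def torque_production_matrix_batch(self, Q: np.ndarray) -> np.ndarray:
        return self.factor * self.base.torque_production_matrix_batch(Q)


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def torque_production_matrix(model: CapabilityModelBase, q: np.ndarray) -> np.ndarray:
    """R(q): 4x9 torque-production matrix of the model at configuration q."""
    return model.torque_production_matrix(q)


def muscle_torque(
    model: CapabilityModelBase, q: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """tau = R(q) alpha for activations alpha in [0, 1]^9."""
    return model.muscle_torque(q, alpha)


def fit_capability_model(
    data: CapabilityDataset, seed: int = 0, n_restarts: int = 5
) -> MuscleCapabilityModel:
    """Fit the semiparametric GPR capability model to a measurement dataset.

    One regressor per muscle group and torque component plus a baseline
    regressor per component; workspace limits are the per-joint min/max of
    the training configurations.
    """
    configs = data.configurations
    if np.unique(np.round(configs, 12), axis=0).shape[0] < 2:
        raise ValueError("need at least 2 distinct configurations to fit")
    reps = data.repetitions
    X = np.repeat(configs, reps, axis=0)
    muscles = []
    for m in range(N_MUSCLES):
        row = []
        for c in range(N_DOF):
            y = data.stimulated[:, m, :, c].reshape(-1)
            row.append(
                _SemiparametricGPR(
                    n_restarts=n_restarts, seed=seed + 7 * m + c
                ).fit(X, y)
            )
        muscles.append(row)
    baseline = [
        _SemiparametricGPR(n_restarts=n_restarts, seed=seed + 100 + c).fit(
            X, data.baseline[:, :, c].reshape(-1)
        )
        for c in range(N_DOF)
    ]
    return MuscleCapabilityModel(
        muscles, baseline, configs.min(axis=0), configs.max(axis=0)
    )


def resample_uncertain_model(
    model: MuscleCapabilityModel,
    data: CapabilityDataset,
    seed: int,
    variance_scale: float = 1.0,
    n_restarts: int = 5,
) -> MuscleCapabilityModel:
    """Refit on training targets drawn from the model's predictive normals.

    Emulates identifying the model from a different noisy experiment: each
    (configuration, muscle, repetition) target is replaced by one draw from
    the posterior predictive at that input, perturbing both the magnitude and
    the joint-space direction of predicted torques.  Deterministic for a
    fixed seed; ``variance_scale=0`` degenerates to refitting the predictive
    means.
    """
    rng = np.random.default_rng(seed)
    configs = data.configurations
    reps = data.repetitions
    n_cfg = configs.shape[0]
    new_base = np.empty_like(data.baseline)
    new_stim = np.empty_like(data.stimulated)
    for c in range(N_DOF):
        mu, sd = model.baseline_regressors[c].predict(configs, return_std=True)
        draws = mu[:, None] + variance_scale * sd[:, None] * rng.standard_normal(
            (n_cfg, reps)
        )
        new_base[:, :, c] = draws
    for m in range(N_MUSCLES):
        for c in range(N_DOF):
            mu, sd = model.muscle_regressors[m][c].predict(configs, return_std=True)
            new_stim[:, m, :, c] = mu[:, None] + variance_scale * sd[
                :, None
            ] * rng.standard_normal((n_cfg, reps))
    new_data = CapabilityDataset(configs, new_base, new_stim)
    return fit_capability_model(new_data, seed=seed, n_restarts=n_restarts)


def sample_training_targets(
    model: MuscleCapabilityModel, data: CapabilityDataset, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One posterior-predictive draw of (baseline, stimulated) targets.

    Same sampling scheme as :func:`resample_uncertain_model` without the
    refit; useful for Monte-Carlo checks of the sampler.
    """
    rng = np.random.default_rng(seed)
    configs = data.configurations
    reps = data.repetitions
    n_cfg = configs.shape[0]
    base = np.empty_like(data.baseline)
    stim = np.empty_like(data.stimulated)
    for c in range(N_DOF):
        mu, sd = model.baseline_regressors[c].predict(configs, return_std=True)
        base[:, :, c] = mu[:, None] + sd[:, None] * rng.standard_normal((n_cfg, reps))
    for m in range(N_MUSCLES):
        for c in range(N_DOF):
            mu, sd = model.muscle_regressors[m][c].predict(configs, return_std=True)
            stim[:, m, :, c] = mu[:, None] + sd[:, None] * rng.standard_normal(
                (n_cfg, reps)
            )
    return base, stim


def fatigue_scaled_model(
    model: CapabilityModelBase, factor: float
) -> ScaledCapabilityModel:
    """Fatigued variant: R_f(q) = factor * R(q), directions preserved."""
    return ScaledCapabilityModel(model, factor)


# ---------------------------------------------------------------------------
# achievable-torque polytope oracles (linear programming)
# ---------------------------------------------------------------------------


def achievable_torque_magnitude(R: np.ndarray, direction: np.ndarray) -> float:
    """Largest t >= 0 with t * direction in {R a : a in [0,1]^9}.

    The achievable torque set is the image of the activation box; this LP
    measures how far it extends along ``direction``.  Returns 0.0 when the
    direction is unreachable at any magnitude.
    """
    from scipy.optimize import linprog

    R = np.asarray(R, dtype=float)
    d = np.asarray(direction, dtype=float).reshape(R.shape[0])
    n = R.shape[1]
    # variables: (a_1..a_n, t); maximize t s.t. R a - t d = 0
    A_eq = np.hstack([R, -d[:, None]])
    c = np.zeros(n + 1)
    c[-1] = -1.0
    bounds = [(0.0, 1.0)] * n + [(0.0, None)]
    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(R.shape[0]), bounds=bounds,
                  method="highs")
    if not res.success:
        return 0.0
    return float(res.x[-1])


def torque_achievable(R: np.ndarray, tau: np.ndarray, tol: float = 1e-9) -> bool:
    """LP membership test: does some a in [0,1]^9 satisfy R a = tau?"""
    from scipy.optimize import linprog

    R = np.asarray(R, dtype=float)
    tau = np.asarray(tau, dtype=float).reshape(R.shape[0])
    n = R.shape[1]
    # minimize sum of equality slacks s with -s <= R a - tau <= s
    A_ub = np.block(
        [[R, -np.eye(R.shape[0])], [-R, -np.eye(R.shape[0])]]
    )
    b_ub = np.concatenate([tau, -tau])
    c = np.concatenate([np.zeros(n), np.ones(R.shape[0])])
    bounds = [(0.0, 1.0)] * n + [(0.0, None)] * R.shape[0]
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    return bool(res.success and res.fun <= tol * max(1.0, np.linalg.norm(tau)))
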