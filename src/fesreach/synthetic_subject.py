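"""Synthetic study subject: ground-truth muscle capabilities and protocol.

The capability measurements of the study participant are not published, so
experiments run against a synthetic subject whose analytic torque-production
field R_true(q) emulates the qualitative features reported for people with
high tetraplegia: a small set of muscle groups with configuration-dependent
strength, at least one group with near-zero strength (lower-motor-neuron
loss), and *weak regions* of the workspace where the achievable torque set
{R_true(q) a : a in [0,1]^9} practically excludes a torque direction, making
those configurations uncontrollable.

The sign structure of R_true is fixed per torque component (agonists versus
antagonists) and the entries are smooth strictly positive modulations of it.
Weakness is configuration dependent: a sigmoid gate of the shoulder-elevation
angle multiplies the whole columns of the arm-raising muscle groups, so past
the gate those muscles are effectively lost and several torque directions
leave the achievable cone entirely.

The module also simulates the capability-measurement protocol (27 grid
configurations, 9 muscle groups plus baseline, 3 repetitions, wrist-force
noise mapped through the arm-Jacobian transpose) and builds the joint-space
target grid used by the planner.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .arm_model import (
    N_DOF,
    N_MUSCLES,
    ArmParameters,
    arm_jacobian_batch,
)
from .muscle_capability import (
    CapabilityDataset,
    CapabilityModelBase,
)

#: joints spanned by the measurement grid (plane of elevation, elevation,
#: elbow flexion); shoulder rotation is only weakly excited by the robot
GRID_JOINTS = (0, 1, 3)

# base sign-and-magnitude pattern (N m at full stimulation), rows are
# (plane of elevation, elevation, shoulder rotation, elbow flexion), columns
# the nine stimulated muscle groups: triceps, deltoids, latissimus dorsi,
# serratus anterior, biceps, supra/infraspinatus, rhomboids, lower
# pectoralis, upper pectoralis
_BASE_PATTERN = np.array(
    [
        [0.2, 0.3, -0.8, 1.2, 0.0, 0.0, -0.6, -0.5, 0.9],
        [0.0, 1.8, -1.2, 0.4, 0.0, 0.3, 0.0, -0.6, 0.7],
        [0.0, 0.2, -0.3, 0.0, 0.2, 1.0, -0.2, -0.8, 0.4],
        [-1.5, 0.0, 0.0, 0.0, 1.8, 0.0, 0.0, 0.0, 0.0],
    ]
)

#: per-muscle overall gains; rhomboids are nearly paralysed
_BASE_GAINS = np.array([1.0, 1.0, 0.9, 0.8, 1.0, 0.9, 0.03, 0.8, 0.9])

_DIFFICULTIES = {
    # gate sharpness (1/rad), gate onset as fraction of the elevation range,
    # and which muscle columns lose strength past the gate
    "easy": {"sharpness": 0.0, "onset": 1.0, "gated": ()},
    "paper-like": {"sharpness": 10.0, "onset": 0.45, "gated": (1, 5, 8)},
    "hard": {"sharpness": 16.0, "onset": 0.40, "gated": (1, 3, 5, 8)},
}

_Q_MIN = np.array([-0.2, 0.2, -0.5, 0.6])
_Q_MAX = np.array([1.2, 1.5, 0.5, 2.0])


class AnalyticCapabilityModel(CapabilityModelBase):
    """Smooth closed-form R_true(q) with gated weak regions."""

    def __init__(
        self,
        magnitudes: np.ndarray,       # (4, 9) signed base entries, N m
        mod_freq: np.ndarray,         # (4, 9, 4) spatial frequencies
        mod_phase: np.ndarray,        # (4, 9)
        mod_depth: float,
        gated_muscles: tuple,         # columns losing strength in the weak region
        gate_joint: int,
        gate_onset: float,
        gate_sharpness: float,
        q_min: np.ndarray,
        q_max: np.ndarray,
    ):
        self.magnitudes = magnitudes
        self.mod_freq = mod_freq
        self.mod_phase = mod_phase
        self.mod_depth = mod_depth
        self.gated_muscles = tuple(gated_muscles)
        self.gate_joint = gate_joint
        self.gate_onset = gate_onset
        self.gate_sharpness = gate_sharpness
        self.q_min = np.asarray(q_min, dtype=float)
        self.q_max = np.asarray(q_max, dtype=float)

    def gate(self, q_gate: np.ndarray) -> np.ndarray:
        """Strength multiplier of gated entries as the gate joint extends."""
        if self.gate_sharpness == 0.0:
            return np.ones_like(np.asarray(q_gate, dtype=float))
        return 1.0 / (1.0 + np.exp(self.gate_sharpness * (q_gate - self.gate_onset)))

    def torque_production_matrix_batch(self, Q: np.ndarray) -> np.ndarray:
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        phase = np.einsum("cik,nk->nci", self.mod_freq, Q) + self.mod_phase
        mod = 1.0 + self.mod_depth * np.sin(phase)          # in (0, 2)
        R = self.magnitudes[None, :, :] * mod                # sign preserved
        if self.gated_muscles:
            g = self.gate(Q[:, self.gate_joint])
            R = R.copy()
            R[:, :, self.gated_muscles] *= g[:, None, None]
        return R


@dataclass
class SyntheticSubject:
    """A simulated study participant.

    Bundles arm parameters (with the passive equilibrium near the workspace
    centre), the ground-truth capability field, workspace limits and the
    force-measurement noise level of the capability protocol.
    """

    parameters: ArmParameters
    r_true: AnalyticCapabilityModel
    noise_std: float
    seed: int
    difficulty: str

    @property
    def q_min(self) -> np.ndarray:
        return self.r_true.q_min

    @property
    def q_max(self) -> np.ndarray:
        return self.r_true.q_max

    @property
    def equilibrium(self) -> np.ndarray:
        return self.parameters.equilibrium_config

    def weak_region_config(self) -> np.ndarray:
        """A configuration well inside the designated weak region."""
        q = self.equilibrium.copy()
        j = self.r_true.gate_joint
        q[j] = min(self.r_true.gate_onset + 0.45, self.q_max[j])
        return q

    def baseline_torque(self, Q: np.ndarray) -> np.ndarray:
        """Unstimulated (passive) torque recorded by the robot, (n, 4)."""
        Q = np.atleast_2d(np.asarray(Q, dtype=float))
        return -self.parameters.joint_stiffness * (
            Q - self.parameters.equilibrium_config
        )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "difficulty": self.difficulty,
            "noise_std": self.noise_std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticSubject":
        return make_ground_truth_subject(
            seed=d["seed"], difficulty=d["difficulty"], noise_std=d["noise_std"]
        )

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "SyntheticSubject":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def make_ground_truth_subject(
    seed: int, difficulty: str = "paper-like", noise_std: float = 1.0
) -> SyntheticSubject:
    """Construct a reproducible synthetic subject.

    ``difficulty`` presets vary the sharpness and onset of the weak-region
    gate: "easy" has no weak region (every direction stays achievable),
    "paper-like" (default) gates the arm-raising muscles at high elevation,
    "hard" gates earlier and also weakens shoulder rotation.
    """
    if difficulty not in _DIFFICULTIES:
        raise ValueError(f"unknown difficulty preset {difficulty!r}")
    preset = _DIFFICULTIES[difficulty]
    rng = np.random.default_rng(seed)

    magnitudes = _BASE_PATTERN * _BASE_GAINS
    magnitudes = magnitudes * (1.0 + 0.1 * rng.uniform(-1, 1, size=(N_DOF, N_MUSCLES)))
    mod_freq = rng.uniform(-1.0, 1.0, size=(N_DOF, N_MUSCLES, N_DOF))
    mod_phase = rng.uniform(0.0, 2 * np.pi, size=(N_DOF, N_MUSCLES))

    gate_joint = 1  # shoulder elevation
    onset = _Q_MIN[gate_joint] + preset["onset"] * (
        _Q_MAX[gate_joint] - _Q_MIN[gate_joint]
    )
    r_true = AnalyticCapabilityModel(
        magnitudes=magnitudes,
        mod_freq=mod_freq,
        mod_phase=mod_phase,
        mod_depth=0.25,
        gated_muscles=preset["gated"],
        gate_joint=gate_joint,
        gate_onset=onset,
        gate_sharpness=preset["sharpness"],
        q_min=_Q_MIN.copy(),
        q_max=_Q_MAX.copy(),
    )
    equilibrium = 0.5 * (_Q_MIN + _Q_MAX)
    params = ArmParameters.from_body_mass(62.0, equilibrium_config=equilibrium)
    return SyntheticSubject(
        parameters=params,
        r_true=r_true,
        noise_std=noise_std,
        seed=seed,
        difficulty=difficulty,
    )


def simulate_capability_experiment(
    subject: SyntheticSubject,
    n_configs: int = 27,
    reps: int = 3,
    seed: int = 0,
) -> CapabilityDataset:
    """Simulate the capability-measurement protocol on the synthetic subject.

    Configurations lie on a grid spanning the workspace over the three most
    mobile joints (3 x 3 x 3 = 27 by default); shoulder rotation receives a
    small seeded excursion about its midpoint.  Each sample is the true
    torque plus wrist-force measurement noise mapped through the
    arm-Jacobian transpose.
    """
    if n_configs < 2:
        raise ValueError("need at least 2 configurations")
    if reps < 1:
        raise ValueError("need at least 1 repetition")
    rng = np.random.default_rng(seed)
    per_axis = max(2, int(round(n_configs ** (1.0 / 3.0))))
    axes = [
        np.linspace(subject.q_min[j], subject.q_max[j], per_axis)
        for j in GRID_JOINTS
    ]
    grid = list(itertools.product(*axes))
    while len(grid) < n_configs:  # degenerate request larger than the cube
        per_axis += 1
        axes = [
            np.linspace(subject.q_min[j], subject.q_max[j], per_axis)
            for j in GRID_JOINTS
        ]
        grid = list(itertools.product(*axes))
    grid = np.asarray(grid[:n_configs])
    mid_rot = 0.5 * (subject.q_min[2] + subject.q_max[2])
    configs = np.empty((n_configs, N_DOF))
    configs[:, list(GRID_JOINTS)] = grid
    configs[:, 2] = mid_rot + rng.uniform(-0.15, 0.15, size=n_configs)

    J = arm_jacobian_batch(configs, subject.parameters)      # (n, 3, 4)
    R_true = subject.r_true.torque_production_matrix_batch(configs)
    base_true = subject.baseline_torque(configs)

    def torque_noise(size):
        force = subject.noise_std * rng.standard_normal(size + (3,))
        return np.einsum("nck,n...c->n...k", J, force)

    baseline = base_true[:, None, :] + torque_noise((n_configs, reps))
    stimulated = (
        base_true[:, None, None, :]
        + np.swapaxes(R_true, 1, 2)[:, :, None, :]
        + torque_noise((n_configs, N_MUSCLES, reps))
    )
    return CapabilityDataset(configs, baseline, stimulated)


def target_grid(
    q_min: np.ndarray, q_max: np.ndarray, spacing: float = np.deg2rad(20.0)
) -> np.ndarray:
    """Joint-space target grid at fixed spacing between the limits.

    Per joint the sequence runs from the minimum to the maximum in steps of
    ``spacing`` (the endpoint is included when it falls on the grid); the
    targets are the Cartesian product in deterministic order (first joint
    slowest).  Returns an (n, 4) array.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    q_min = np.asarray(q_min, dtype=float)
    q_max = np.asarray(q_max, dtype=float)
    axes = []
    for j in range(N_DOF):
        n_steps = int(np.floor((q_max[j] - q_min[j]) / spacing + 1e-9))
        axes.append(q_min[j] + spacing * np.arange(n_steps + 1))
    return np.array(list(itertools.product(*axes)))
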