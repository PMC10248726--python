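"""Simulation study: condition matrix, error metrics and group comparisons.

The study asks whether dynamics-aware trajectory planning is necessary for
FES-driven reaching.  For a set of reachable targets it compares planned
versus direct-to-target paths under three controllers (FB, FFFB, MPC) and
three plant/controller model relationships:

* *ideal* — the controller's capability model is the plant's model;
* *uncertain* — the controller uses a model refitted to posterior-predictive
  resamples of the training data (one resampled model per repeat, shared by
  all trajectories of that repeat);
* *fatigued* — the plant's torque production is scaled to 90% of the model
  the controller believes in.

Outcome metrics per reach: joint-space error (Euclidean distance of the
final configuration from the target configuration) and Cartesian error (3-D
Euclidean distance of the final wrist position from the target position).
Aggregates: the number of targets within a 5 cm error threshold, mean and
standard deviation of errors, benchmark curves (fraction of reaches below a
sliding error bound), and rank-based (Kruskal-Wallis) comparisons of
planned versus direct errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .arm_model import ArmParameters, ArmState, forward_kinematics
from .controllers import MpcConfig, PidGains, ReachOutcome, run_closed_loop
from .muscle_capability import (
    CapabilityDataset,
    CapabilityModelBase,
    MuscleCapabilityModel,
    fatigue_scaled_model,
    fit_capability_model,
    resample_uncertain_model,
)
from .planning import (
    Trajectory,
    TrajectoryOptimizationSpec,
    inverse_dynamics_activations,
    quintic_direct_trajectory,
    solve_reach_nlp,
)
from .synthetic_subject import (
    SyntheticSubject,
    make_ground_truth_subject,
    simulate_capability_experiment,
    target_grid,
)

CONDITIONS = ("ideal", "uncertain", "fatigued")


@dataclass
class ExperimentConfig:
    """Study configuration; defaults mirror the simulation protocol."""

    subject_seed: int = 1
    difficulty: str = "paper-like"
    noise_std: float = 1.0
    n_targets: int = 30
    strategies: tuple = ("FB", "FFFB", "MPC")
    conditions: tuple = CONDITIONS
    n_repeats: int = 10          # uncertain-model repeats
    fatigue_factor: float = 0.9
    error_threshold: float = 0.05  # m
    n_nodes: int = 100
    gpr_restarts: int = 5
    seed: int = 0
    min_reach_distance: float = 0.02  # m, skip targets at the start position

    def __post_init__(self):
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class Study:
    """Prepared inputs shared by every cell of the condition matrix."""

    subject: SyntheticSubject
    dataset: CapabilityDataset
    nominal_model: MuscleCapabilityModel
    targets: np.ndarray                 # (n_targets, 4)
    planned: list                       # Trajectory per target
    direct: list                        # Trajectory per target
    alpha_ff_direct: list               # (n, 9) or None per target
    direct_ff_feasible: list            # bool per target
    manifest: pd.DataFrame              # full target-grid feasibility table

    @property
    def parameters(self) -> ArmParameters:
        return self.subject.parameters


@dataclass
class ExperimentReport:
    """Per-reach rows plus the configuration that produced them."""

    rows: pd.DataFrame
    config: ExperimentConfig

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, config: Optional[ExperimentConfig] = None):
        return cls(pd.read_csv(path), config or ExperimentConfig())


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def reach_errors(
    outcome: ReachOutcome, target_q: np.ndarray, p: ArmParameters
) -> tuple[float, float]:
    """(joint error rad, Cartesian error m) of the final state vs target."""
    q_final = outcome.states[-1, :4]
    target_q = np.asarray(target_q, dtype=float)
    joint = float(np.linalg.norm(q_final - target_q))
    cart = float(
        np.linalg.norm(
            forward_kinematics(q_final, p) - forward_kinematics(target_q, p)
        )
    )
    return joint, cart


def benchmark_curve(errors: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Fraction of reaches with error <= b for each benchmark b in grid."""
    errors = np.asarray(errors, dtype=float)
    return np.array([np.mean(errors <= b) for b in np.asarray(grid)])


def compare_groups(errors_a, errors_b) -> tuple[float, float]:
    """Kruskal-Wallis rank test between two error samples: (H, p).

    Midranks handle ties; two identical samples give H = 0, p = 1.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, pval = stats.kruskal(a, b)
    return float(H), float(pval)


# ---------------------------------------------------------------------------
# study preparation (planner manifest, direct paths, feedforward)
# ---------------------------------------------------------------------------


def prepare_study(
    cfg: ExperimentConfig,
    targets: Optional[np.ndarray] = None,
    progress: bool = False,
) -> Study:
    """Build the subject, fit the capability model, and plan all reaches.

    ``targets`` overrides the default workspace grid (useful for scaled-down
    runs); reaches start from the passive equilibrium at rest.  Planning
    failures are recorded in the manifest and the corresponding targets
    dropped, mirroring abandoning unreachable grid points.
    """
    subject = make_ground_truth_subject(
        cfg.subject_seed, cfg.difficulty, cfg.noise_std
    )
    dataset = simulate_capability_experiment(subject, seed=cfg.subject_seed + 1)
    nominal = fit_capability_model(
        dataset, seed=cfg.seed, n_restarts=cfg.gpr_restarts
    )
    p = subject.parameters
    x0 = ArmState.at_rest(subject.equilibrium)
    start_wrist = forward_kinematics(x0.q, p)
    if targets is None:
        targets = target_grid(nominal.q_min, nominal.q_max)
    records = []
    kept_t, kept_planned, kept_direct, kept_ff, kept_ok = [], [], [], [], []
    for i, qt in enumerate(np.atleast_2d(targets)):
        reach_len = float(
            np.linalg.norm(forward_kinematics(qt, p) - start_wrist)
        )
        if reach_len < cfg.min_reach_distance:
            records.append((i, *qt, "skipped", np.nan, reach_len))
            continue
        spec = TrajectoryOptimizationSpec.for_reach(
            nominal, x0, qt, n_nodes=cfg.n_nodes, retry_seed=cfg.seed + i
        )
        traj = solve_reach_nlp(spec, nominal, p)
        records.append(
            (i, *qt, traj.status, traj.objective, reach_len)
        )
        if traj.status != "feasible":
            continue
        if len(kept_t) >= cfg.n_targets:
            continue
        direct = quintic_direct_trajectory(
            x0.q, qt, spec.duration, cfg.n_nodes
        )
        aff, ok = inverse_dynamics_activations(direct, nominal, p)
        kept_t.append(qt)
        kept_planned.append(traj)
        kept_direct.append(direct)
        kept_ff.append(aff)
        kept_ok.append(ok)
        if progress:
            print(f"target {i}: feasible ({len(kept_t)}/{cfg.n_targets})")
    manifest = pd.DataFrame(
        records,
        columns=["target", "q0", "q1", "q2", "q3", "status", "objective",
                 "reach_length_m"],
    )
    return Study(
        subject=subject,
        dataset=dataset,
        nominal_model=nominal,
        targets=np.asarray(kept_t),
        planned=kept_planned,
        direct=kept_direct,
        alpha_ff_direct=kept_ff,
        direct_ff_feasible=kept_ok,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# condition matrix
# ---------------------------------------------------------------------------


def _controller_models(
    cfg: ExperimentConfig, study: Study
) -> dict[str, list[tuple[int, CapabilityModelBase, CapabilityModelBase]]]:
    """(repeat, plant, controller) triples per condition."""
    nominal = study.nominal_model
    out: dict[str, list] = {}
    if "ideal" in cfg.conditions:
        out["ideal"] = [(0, nominal, nominal)]
    if "uncertain" in cfg.conditions:
        out["uncertain"] = [
            (
                r,
                nominal,
                resample_uncertain_model(
                    nominal, study.dataset, seed=cfg.seed + 1000 + r,
                    n_restarts=cfg.gpr_restarts,
                ),
            )
            for r in range(cfg.n_repeats)
        ]
    if "fatigued" in cfg.conditions:
        out["fatigued"] = [
            (0, fatigue_scaled_model(nominal, cfg.fatigue_factor), nominal)
        ]
    return out


def run_condition_matrix(
    cfg: ExperimentConfig,
    study: Optional[Study] = None,
    pid: Optional[PidGains] = None,
    mpc: Optional[MpcConfig] = None,
    progress: bool = False,
) -> ExperimentReport:
    """Execute every (target, path type, strategy, condition, repeat) cell.

    The plant always simulates the nominal capability model (scaled in the
    fatigued condition); the controller sees the condition's model.
    Individual reach failures are recorded with NaN errors, not fatal.
    """
    study = study or prepare_study(cfg, progress=progress)
    models = _controller_models(cfg, study)
    p = study.parameters
    rows = []
    for ti, qt in enumerate(study.targets):
        paths = {"planned": study.planned[ti], "direct": study.direct[ti]}
        ff = {
            "planned": study.planned[ti].activations,
            "direct": study.alpha_ff_direct[ti],
        }
        for cond, triples in models.items():
            for repeat, plant, controller in triples:
                for strat in cfg.strategies:
                    for path_type, traj in paths.items():
                        try:
                            outcome = run_closed_loop(
                                strat, plant, controller, traj, p,
                                alpha_ff=ff[path_type] if strat == "FFFB" else None,
                                pid=pid, mpc=mpc,
                            )
                            jerr, cerr = reach_errors(outcome, qt, p)
                            stuck = outcome.stuck
                        except RuntimeError as err:
                            jerr = cerr = float("nan")
                            stuck = True
                            if progress:
                                print(f"reach failed: {err}")
                        rows.append({
                            "target": ti,
                            "path": path_type,
                            "strategy": strat,
                            "condition": cond,
                            "repeat": repeat,
                            "joint_error_rad": jerr,
                            "cartesian_error_m": cerr,
                            "stuck": stuck,
                            "direct_ff_feasible": study.direct_ff_feasible[ti],
                        })
                if progress:
                    print(f"target {ti} {cond} repeat {repeat} done")
    return ExperimentReport(pd.DataFrame(rows), cfg)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------


def summarize(
    report: ExperimentReport,
    threshold: Optional[float] = None,
    benchmark_grid: Optional[np.ndarray] = None,
) -> dict:
    """Aggregate tables: target counts, mean errors, curves, tests.

    For the uncertain condition the per-target error is first averaged over
    repeats, then aggregated, so each target contributes one number per
    cell.  Returns a dict with ``table`` (per condition/strategy/path),
    ``curves`` (benchmark fractions) and ``tests`` (planned vs direct
    Kruskal-Wallis p-values).
    """
    cfg = report.config
    threshold = cfg.error_threshold if threshold is None else threshold
    if benchmark_grid is None:
        benchmark_grid = np.arange(0.02, 0.201, 0.01)  # 2 - 20 cm
    df = report.rows
    per_target = (
        df.groupby(["condition", "strategy", "path", "target"])
        ["cartesian_error_m"].mean().reset_index()
    )
    per_target_joint = (
        df.groupby(["condition", "strategy", "path", "target"])
        ["joint_error_rad"].mean().reset_index()
    )
    table_rows, curve_rows, test_rows = [], [], []
    for (cond, strat, path), g in per_target.groupby(
        ["condition", "strategy", "path"]
    ):
        errs = g["cartesian_error_m"].to_numpy()
        jg = per_target_joint.query(
            "condition == @cond and strategy == @strat and path == @path"
        )["joint_error_rad"].to_numpy()
        table_rows.append({
            "condition": cond,
            "strategy": strat,
            "path": path,
            "n_targets": len(errs),
            "n_within_threshold": int(np.sum(errs <= threshold)),
            "mean_cartesian_error_m": float(np.nanmean(errs)),
            "sd_cartesian_error_m": float(np.nanstd(errs)),
            "mean_joint_error_rad": float(np.nanmean(jg)),
        })
        curve_rows.append({
            "condition": cond, "strategy": strat, "path": path,
            "benchmark_m": benchmark_grid,
            "fraction": benchmark_curve(errs, benchmark_grid),
        })
    for (cond, strat), g in per_target.groupby(["condition", "strategy"]):
        a = g.query("path == 'planned'")["cartesian_error_m"].to_numpy()
        b = g.query("path == 'direct'")["cartesian_error_m"].to_numpy()
        if a.size and b.size:
            H, pval = compare_groups(a, b)
            test_rows.append({
                "condition": cond, "strategy": strat,
                "H": H, "p_value": pval,
            })
    return {
        "table": pd.DataFrame(table_rows),
        "curves": pd.DataFrame(curve_rows),
        "tests": pd.DataFrame(test_rows),
        "threshold": threshold,
    }
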