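# Methods

`fesreach` simulates and plans reaching motions of a paralyzed arm driven by
functional electrical stimulation (FES), for a person whose muscle
capabilities have been measured experimentally. This note documents the
models, the numerical choices, and what the synthetic test bed does and does
not establish.

## Arm model

The arm is a two-link chain (humerus 0.315 m, forearm 0.253 m) with four
degrees of freedom: an ISB-style mobile Y–X–Y′ shoulder sequence — plane of
elevation about the thorax vertical, elevation about the rotated x axis,
internal rotation about the humeral long axis — and an elbow-flexion hinge
about the humeral local x axis. One rotation-matrix composition (in
`arm_model._chain`) is shared by the forward kinematics, the wrist Jacobian
and the dynamics. Forearm pronation is excluded from the dynamic model: a
pure pronation produces no force at the wrist, so the capability protocol
cannot observe it.

Dynamics are kept in implicit state-space form

    f(x, ẋ, α) = [ q̇ − ω ;
                   M(q) ω̇ + C(q, ω) ω + D ω + K (q − q_eq) + g(q) − R(q) α ]

with x = (q, ω). Inertial parameters default to anthropometric segment
fractions of a configurable total body mass (62 kg); none of the shipped
results depend on their exact values, because the passive joint stiffness
K = 1 N·m/rad and damping D = 1 N·m·s/rad (about the measured passive
equilibrium) dominate this lightweight, gravity-free system. Gravity is off
by default — the intended user wears a mobile arm support assumed to
compensate it perfectly — but can be switched on.

Rather than generating symbolic equations of motion, M(q) is assembled
exactly from per-body point Jacobians, and the Coriolis vector from
Christoffel symbols whose ingredient ∂M/∂q is obtained by complex-step
differentiation of the (holomorphic) mass-matrix code; both are exact to
machine precision. The residual Jacobians ∂f/∂ẋ and the velocity part of
∂f/∂x are likewise exact; the configuration part uses central differences
(step 1e-6 rad) of machine-precision quantities, and ∂R/∂q uses central
differences with step 1e-4 rad — the capability model is a smoothed
regressor whose analytic derivative would add complexity without accuracy
the planner needs. All Jacobians are validated against finite differences
of `f` at randomized states (1e-5 relative).

Time stepping is backward Euler with a damped Newton iteration (analytic
Jacobian, residual tolerance 1e-10, 50 iterations, step halving on residual
increase). Newton updates are capped at 0.5 (inf-norm): at large steps the
implicit equation can have several roots where the capability field is
steep, and the cap keeps the iteration on the root adjacent to the previous
state, which is the one the continuous flow visits. Activations are held
constant across each step, matching how a stimulator updates at a fixed
pulse rate.

## Muscle capability model

Nine muscle groups are stimulated at fixed maximum parameters; activation
α ∈ [0,1]⁹ is the fraction of that maximum, and torques combine linearly:
τ = R(q)α, with column i of the 4×9 matrix R(q) the torque of group i at
full activation. R(q) is identified from a capability experiment: at 27
grid configurations, wrist force is recorded with no stimulation (baseline)
and per group, three repetitions each, and mapped to joint torques through
the wrist-Jacobian transpose.

Each torque component of each group — and of the baseline — is fitted by a
semiparametric Gaussian-process regression: a parametric mean linear in
[1, q, sin q, cos q] (periodic features suit joint angles) plus a zero-mean
GP residual with an anisotropic squared-exponential kernel and a white-noise
term, hyperparameters by marginal-likelihood maximization with 5 random
restarts (fixed seed). The predicted muscle contribution is the stimulated
prediction minus the baseline prediction, evaluated at the same
configuration. In the noiseless limit the fit interpolates, and a
structurally linear-in-features truth is reproduced by the mean function
alone. Workspace limits are the per-joint min/max of the training
configurations.

Two derived model variants feed the robustness studies:

* **uncertain** — new training targets are drawn from the posterior
  predictive (mean and variance) at the training inputs, one draw per
  (configuration, muscle, repetition), and the model is refitted, perturbing
  both magnitude and joint-space direction of each predicted column;
* **fatigued** — R is scaled by a constant factor (default 0.9), shrinking
  magnitudes while preserving directions.

## Synthetic subject

The real participant's capability data are not published, so experiments
run against a synthetic subject with an analytic ground-truth field
R_true(q). Its structure encodes the clinical picture qualitatively: a
fixed agonist/antagonist sign pattern per torque component with smooth
strictly-positive modulations (depth 0.25), one near-paralyzed group
(rhomboids, 3% gain), and a *weak region*: a sigmoid gate of the
shoulder-elevation angle multiplies the whole columns of the arm-raising
groups (deltoids, supra/infraspinatus, upper pectoralis), so past the gate
several torque directions leave the achievable set {R(q)α : α ∈ [0,1]⁹}
entirely — linear programming certifies, e.g., that upward elevation and
shoulder-rotation torque become unavailable at any useful magnitude, while
all ±coordinate directions are achievable at the workspace centre.
Difficulty presets vary the gate (none / default / earlier+sharper with an
extra gated group). The gate onset sits slightly below the equilibrium
elevation so a controller can push the arm into the degenerate zone — this
is what makes "stuck" behaviour reachable in simulation.

The simulated protocol measures baseline and per-group samples on a
3×3×3 grid over the three most mobile joints (plane of elevation,
elevation, elbow), with a small seeded excursion of shoulder rotation about
its midpoint, and adds per-axis wrist-force noise (default 1 N, a plausible
load-cell scale) mapped through Jᵀ. What the generator does **not**
emulate: activation dynamics and electromechanical delay, fatigue over
time, spasticity, day-to-day variability, and measurement nonstationarity.
Tests passing on this subject show the pipeline is correct and that the
qualitative phenomena (infeasible direct paths, stuck configurations,
planning benefit) emerge — not that error magnitudes measured on any real
participant would transfer.

## Trajectory planning

Direct-to-target references are per-joint quintic (minimum-jerk) profiles
from rest to rest. Planned references solve a direct-collocation NLP over
node states and activations:

    minimize   mean(α²) + γ · mean((q − q_targ)²)         γ = 1 rad⁻²
    subject to per-node state bounds (training range ± 11°, |ω| ≤ 10 rad/s),
               α ∈ [0,1]⁹,
               f(x_{k+1}, (x_{k+1} − x_k)/dt, α_k) = 0,
               x_1 = (q_0, 0),  x_n = (q_targ, 0).

The defect uses the simulator's own discretization — backward Euler with
the activation held at the earlier node — so a feasible solution replays
exactly through the simulator; this matched-discretization choice is the
package's principal end-to-end oracle. With the default n = 100 nodes over
2 s the step is duration/(n−1) ≈ 0.0202 s; the nominal 0.02 s figure is
treated as rounded, resolving the off-by-one between node count, step and
duration.

The NLP is solved with scipy's `trust-constr` using an analytic sparse
defect Jacobian, the exact (diagonal) objective Hessian, and defect rows
scaled by dt to balance the rate and torque equations. The boundary states
are eliminated from the decision vector rather than pinned by equal bounds,
which the interior-point handling tolerates poorly. Because the barrier
method keeps polishing the objective long after feasibility, a callback
stops the solver 150 iterations after the scaled violation first drops
below 3e-7 (overall cap 1500 iterations). A solution is accepted as
feasible only if (a) the defect violation is ≤ 1e-6 and (b) forward
re-integration of its activations from the start state lands within 1e-3
rad of the target; the re-integrated states are stored, making the stored
trajectory exactly simulator-consistent. The replay check also guards
against a coarse-step pathology: at dt ≈ 0.05 s the implicit equations can
admit non-physical roots that let the NLP "teleport" between velocity
branches; such solutions are rejected and effectively disappear at the
production step of 0.02 s.

The default initial guess is the quintic path with zero activation; on
failure, one retry uses a seeded random guess (linear interpolation ± 0.1
rad, activations U[0, 0.3]); failing again, the target is abandoned.
Abandonment does not prove infeasibility.

Feedforward activations for an arbitrary reference are recovered by
inverse dynamics: the path is re-discretised with the simulator's rule
(backward-difference velocities, starting at rest), the required interval
torque computed, and a minimum-norm activation found per interval by the
same QP the controllers use; if any interval is unachievable the reach is
flagged and all-zero feedforward returned.

The node count for a given accuracy is selected by refinement: solve a
200-node reference, then increase the count from 10 (steps of 10) until the
optimized wrist path, cubic-spline resampled onto the reference time grid,
deviates by at most 1 mm rms. The comparison is in hand space because the
tolerance is metric. Every refinement solve starts from the same quintic
default guess; identical initialization keeps the solver's stopping bias
correlated between candidate and reference so that their rms difference is
dominated by discretization. The refinement history can still show scatter
from solves that land on different local optima; termination certifies
millimetre agreement of the selected solve with the reference, and the
non-strict mode reports the best rms achieved when no tried count meets
the tolerance.

## Controllers

All controllers run at the trajectory's node rate and see only the
*controller's* capability model evaluated at the measured configuration;
the plant simulates with its own (possibly different) model.

* **FB** — joint-space PID (Kp = 10 N·m/rad, Kd = 1 N·m·s/rad, Ki = 1
  N·m/(rad·s); the printed gain units are interpreted as joint-torque
  gains, since the controller outputs torques). The integral is clamped at
  ±1 rad·s to prevent windup while the fallback outputs zeros. Muscle
  redundancy is resolved by min ‖α‖² s.t. R(q)α = τ_FB, α ∈ box — solved
  as an LP feasibility certificate (HiGHS) followed by an SLSQP polish on
  an SVD-reduced equality system (R may be rank deficient). If the request
  is unachievable, it is shrunk to 70% repeatedly (≤ 10 scalings,
  direction preserved); exhausted, the controller outputs zero activation —
  the "stuck" mechanism.
* **FFFB** — the same loop plus feedforward activations (planner output
  for planned paths, inverse dynamics for direct paths); the QP box becomes
  α_fb + α_ff ∈ [0,1]⁹ and on exhaustion the feedforward alone passes
  through.
* **MPC** — incremental MPC: the implicit dynamics are linearized at the
  current state and previously applied activation (A_c = −(∂f/∂ẋ)⁻¹∂f/∂x,
  B_c likewise), discretized by exact zero-order hold (augmented matrix
  exponential, including an affine drift so predictions follow the
  nonlinear flow to first order), and augmented with the previous
  activation so the decision variables are increments Δα. Horizons ny = 4,
  nu = 2, increment weight λ = 0.001; output = joint angles only; the
  reference extends past the trajectory end by holding the final target.
  The box constraint on cumulative activation is enforced inside the QP
  (hard constraints are the point of MPC here): substituting cumulative
  activations as variables turns it into a box-QP solved exactly by the
  normal equations when the unconstrained optimum is interior, else by
  bounded L-BFGS-B.

## Experiments

A study tests every combination of path type (planned / direct), strategy
(FB / FFFB / MPC) and model condition (ideal; uncertain × 10 repeats, one
resampled controller model per repeat shared across trajectories; fatigued,
plant scaled to 0.9 of the controller's model) over a set of feasible
targets reached from the passive equilibrium. Outcomes per reach: joint
error ‖q_final − q_targ‖₂ and Cartesian wrist error; aggregates: targets
within 5 cm, mean ± sd (uncertain errors averaged over repeats per target
first — the aggregation level is configurable), benchmark curves over 2–20
cm, and Kruskal–Wallis rank tests of planned vs direct errors (implemented
as the general k-group statistic with midranks, which reduces to the
rank-sum test for two groups).

## Problem sizes and tolerances used in the shipped tests

The test-suite and acceptance runs use the full measurement protocol
(27 × 3 × 9 + baseline) but scale the control study down to a handful of
targets, 40–100 nodes and reduced GPR restarts, sizes chosen to exercise
every phenomenon (feasible and abandoned targets, stuck reaches, planning
benefit) with wall-clock budgets appropriate for a test suite. The node
refinement and exact-replay checks run at full 100/200-node resolution.
Key tolerances: Newton residual 1e-10; defect acceptance 1e-6 with replay
polish; Jacobian validation 1e-5 relative; QP equality residual 1e-6;
noiseless capability recovery 1e-3 N·m.

## Known limitations

* No muscle force–length/velocity properties, activation dynamics, or
  delays; activation-to-torque is instantaneous and linear.
* The NLP solver is a general-purpose interior-point method; it is slower
  than a specialized sparse SQP and an "abandoned" label is solver
  failure, not a feasibility certificate.
* The uncertain-model resampling refits hyperparameters per repeat, which
  is expensive; reduced restarts are used in tests.
* The synthetic subject's weak region is a one-parameter gate on
  elevation; real capability loss is higher dimensional.
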