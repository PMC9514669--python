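# Methods

## The estimation problem

`ocdspe` estimates the hidden states x(t) and fixed parameters Θ of a
nonlinear ODE model

    dx/dt = f(x, Θ),          x ∈ R^D,

from short, noisy, *partial* observations y(t_n) = H x(t_n) + r(t_n),
r ~ N(0, σ²), where the diagonal 0/1 operator H exposes only L ≤ D
components.  The regime of interest is the hard one: chaotic or spiking
dynamics, few observed components, nonlinear parameters, uninformative
(two-orders-of-magnitude) parameter bounds.

Four methods are implemented on one discretization and one annealing
driver:

1. **Nudging** (`nudge`): fixed-gain synchronization
   dx/dt = f + U(y − Hx) with constant diagonal gain U.  Requires known Θ;
   serves as the state-estimation baseline and as the smoother behind the
   cost-surface scans.
2. **Constrained least squares / variational annealing** (`method="lsq"`):
   minimize Σ_n ‖Hx(t_n) − y(t_n)‖² subject to the model dynamics,
   enforced as annealed penalties.
3. **DSPE** (`method="dspe"`): add time-dependent gains U_l(t_n) on the
   observed components as free variables, constrain the *controlled*
   dynamics, and penalize Σ_n ‖U(t_n)‖² in the cost.
4. **OC-DSPE** (`method="ocdspe"`): eliminate the gains via the Pontryagin
   minimum principle.  The stationarity of the control Hamiltonian gives
   U_ll = −p_l (y − Hx)_l, and Hamilton's equations yield the *estimation
   dynamics* over states and conjugate momenta p:

       dx_d/dt = f_d(x, Θ) − p_d ([y − Hx]_d)²
       dp_d/dt = −(∂f/∂x_d)·p + [Hᵀ(y − Hx)]_d (1 − p_d²)

   with the transformed cost  Σ_l ½ (y − Hx)_l² (1 + p_l²).  The momenta
   measure the marginal cost of violating the dynamics; their average
   magnitude doubles as a quality diagnostic (`momentum_diagnostic`).

## Discretization

Dynamics constraints are discretized per interval with compressed
Hermite–Simpson quadrature:

    g_n = z_{n+1} − z_n − (dt/6)(φ_n + 4 φ_mid + φ_{n+1}),
    z_mid = (z_n + z_{n+1})/2 + (dt/8)(φ_n − φ_{n+1}),

exact for cubic-in-time solutions (local order 5).  The compressed variant
(midpoint eliminated through the Hermite interpolant) was chosen over
separated collocation to keep the search space at D·N (+ D·N momenta for
OC-DSPE) without extra midpoint unknowns.  Time-dependent inputs
(observations, stimulus, DSPE control paths) are evaluated at midpoints by
linear interpolation.

The *residual of the constraint equation* at t_n is the defect divided by
dt — the constraint is a rate equation (dz/dt − φ = 0), so its
discretization carries rate units.  Equivalently, the quadratic penalty
applies R_i/dt² to the raw defect.  This normalization matters: with
defect-unit residuals the penalty at the final annealing weight is too
weak to forbid solutions that track observation noise while loosely
satisfying the dynamics, and those spurious solutions would also hijack
best-run selection (they reach artificially low measurement error E).

## Penalty annealing

All three optimizing methods minimize

    C(β) = C_method(·) + λ0 α^β Σ_{i,n} R_i g_{i,n}²,   β = 0 … β_max,

with λ0 = 1, α = 2, β_max = 24 by default, warm-starting each β at the
previous optimum (homotopy continuation from the data-fitting problem to
the dynamics-constrained one).  Per-equation scales R_i normalize the
contribution of variables with different dynamic ranges: for Lorenz96
R_i = 10⁻⁴ for every equation; for the neuron R_V = 10⁻⁴, R_w = 1 and
R_pV = R_pw = 1 for the OC-DSPE momenta equations.

The inner solver is bound-constrained L-BFGS-B with exact first
derivatives.  Derivatives are exact because the models are stored as sympy
expressions: the state/parameter/control Jacobians of every constraint
field (including the estimation dynamics, whose momenta equations contain
second derivatives of f) are generated symbolically and compiled to
vectorized numpy, and the chain rule through the Hermite–Simpson midpoint
is a hand-derived adjoint verified against central finite differences at
rtol 1e-5 in the test suite.

Two numerical safeguards around L-BFGS-B, both verified necessary on the
neuron problems:

* **Objective normalization.**  Each β-solve optimizes s·C(β) with
  s = 1/max(1, C(β) at the warm start).  The Fortran line search makes no
  progress when f and |∇f| sit many orders of magnitude above 1, which is
  the generic situation at a random neuron-model start.
* **Variable scaling.**  The solver works on v/scale, with per-class
  scales taken from the box widths (voltages O(100), gating variables and
  momenta O(1), conductances O(100)).  L-BFGS-B has no preconditioner, and
  mixing mV-scale and O(1) coordinates in one path vector stalls progress
  on the small ones.

Residuals that overflow at extreme sampled kinetics (cosh of a large
argument when a gating slope γ is drawn near its lower bound) are capped
at 10⁶, keeping the penalty finite and strongly repelling without
changing it anywhere sane.

## Initialization and multistart

Each of Q independent runs draws states uniformly within their bounds
(Lorenz96 ±15; V ∈ [−100, 100], w ∈ [0, 1]), parameters uniformly within
their bounds, DSPE controls uniformly in [0, 100], and momenta uniformly
from their *presumed dynamical range* (default [−1, 1]; the search bounds
stay [−100, 100]).  The presumed range matters: consistent momenta are
O(1) or smaller, and starts drawn across the full ±100 box either stall
the line search or push the momenta into a runaway basin where p
saturates its bounds to absorb arbitrary state defects.  For the neuron
experiments the momenta start at 0.

The best run is the one with the lowest measurement error
E = Σ_n ‖Hx̂(t_n) − y(t_n)‖², with ties broken by final residual norm and
then run index.  E-selection presumes the runs end near
constraint-feasibility — one more reason for the rate-unit penalty above.

## Parameter bounds

Positive parameters (conductances, capacitance, φ_w, gating slopes γ)
are bounded [0.01, 200], spanning two orders of magnitude around the
truth.  Reversal potentials and half-activation voltages are
sign-carrying and get [−200, 200]; a positive-only box could not contain
E_K = −100 mV.  Lorenz96's forcing is bounded [1, 20].  Bounds are
per-parameter configurable (`BoundsSpec.params`).

## Ground-truth models and units

*Lorenz96* (D ≥ 4, cyclic): dx_d/dt = (x_{d+1} − x_{d−2}) x_{d−1} − x_d + F,
chaotic near F ≈ 8.  Twin experiments use D = 10, 501 samples at
dt = 0.016 after a 10-time-unit transient so data lie on the attractor.

*Morris-Lecar* (K+Na): C dV/dt = −g_fast m∞(V)(V−E_Na) − g_slow w(V−E_K)
− g_leak(V−E_leak) + I_stim;  dw/dt = φ_w (w∞(V) − w)/τ_w(V), with
tanh/cosh gating curves.  Ground truth: C = 2.5, g_fast = 20, g_slow = 15,
g_leak = 2, E_Na = 50, E_K = −100, E_leak = −70, φ_w = 0.12, β_w = 0,
β_m = −1.2, γ_m = 18, γ_w = 10.  The numbers form a consistent
mV/ms/pA-compatible unit system and are used as printed, without
conversion.  The persistent-sodium variant adds −g_NaP m∞(V)(V−E_NaP)
with g_NaP = 3, E_NaP = 50 and is used only to generate *misspecified*
data (fit a K+Na model to K+Na+NaP observations).

Neuron data are generated over [0, 100] ms at dt = 0.05 ms after a 50 ms
transient, under either a 100 pA step or a chaotic current
I(t) = 20·|x₁(t/15)| built from one component of a 10D Lorenz96 run —
a persistently varying stimulus that pushes the neuron across limit-cycle
manifolds and makes the kinetic parameters identifiable.

## What the synthetic-data generator emulates — and what it does not

Measurement noise is i.i.d. Gaussian on the observed rows only, with
known, constant σ — the in-vitro intracellular-recording situation.
Process noise (`integrate_process_noise`) adds a fresh N(0, SD²) current
draw on each dt step of a fixed-step RK4 integration, held constant
across the step and *not* rescaled by √dt: that is the convention under
which SD = 10/50/100 pA at dt = 0.05 ms is meaningful, and the recorded
dt in the metadata keeps the noise model interpretable.  Not emulated:
colored or state-dependent noise, non-Gaussian error, time-varying σ,
unknown or non-diagonal H, multi-compartment or network neurons.  Passing
tests therefore demonstrate correctness of the estimators under the
stated generative model, not robustness to real electrophysiology.

## Desk-scale study sizes

The printed experiments used 100 initializations × 100 data windows
(Lorenz96) and 25 initializations (neuron) with effectively unbounded
optimizer depth.  This package's acceptance runs use the same data sizes
(Lorenz96: N = 501 at dt = 0.016; neuron: [0, 100] ms generated at
dt = 0.05 ms) with Q = 20 Lorenz96 / Q = 5 neuron initializations.
L-BFGS-B depth per annealing step is capped at 120 (Lorenz96 DSPE/least
squares), 90 (Lorenz96 OC-DSPE, which locks onto the forcing early),
1500 (neuron restricted conductance fits, where depth trims the
noise-tracking bias), and 500 (the 11-parameter neuron fit, which does
not improve with depth at this scale — see below).  The neuron
estimations run on a decimated copy of the observations (every second
sample, dt_est = 0.1 ms; Hermite–Simpson at order 5 loses little at this
resolution).  Full-scale dispersion histograms over 100 data windows are
out of scope.

Known consequences of the capped depth on the neuron problems: the final
residual norm settles around 10–30 (defect·dt⁻¹ units) rather than
machine-level, and parameter estimates retain a percent-level bias toward
noise-tracking (e.g. the slow conductance lands a little below truth).
The Lorenz96 experiments are insensitive to this: the best-run forcing
estimates reproduce the generative values to well under 1%.

The full 11-parameter neuron fit under the chaotic current is a known
limitation at desk scale.  Its search space contains a *frozen-gate*
family of local optima (φ_w and g_slow driven to their lower bounds, so
the gating variable never engages and the model degenerates to a
fast+leak neuron) that satisfies the annealed constraints well while
sitting far from the generative parameters.  Annealing initialized at
the truth stays near the truth — the correct basin exists and is
self-consistent — but within this package's single-core iteration budget
random initializations land in the degenerate family instead, and runs
that fail this way can end with a *lower* measurement error E than
honest ones, defeating lowest-E selection.  Recovering this experiment
appears to need the original multistart count (25) at effectively
unbounded per-β optimizer depth.  Restricted fits (conductances only,
kinetics frozen) do not suffer from this and recover reliably.

## Degenerate inputs and edge rules

σ = 0 reproduces H x exactly; a zero-length prediction grid returns the
initial state; nudging with all gains zero equals free integration;
DSPE with control bounds collapsed to [0, 0] is exactly the least-squares
objective.  Cost scans record +∞ where the forward integration fails.
Strict local minima on a grid are interior points lower than both
neighbors — endpoints excluded — which is what makes "rugged versus
convex cost section" claims testable.
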