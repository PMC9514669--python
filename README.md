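# ocdspe

Joint inference of hidden dynamical states and fixed parameters in
nonlinear — including chaotic and spiking — ODE models, from short, noisy,
partially observed time series.

The package is built for the twin-experiment workflow used in systems
biology and computational neuroscience: synthesize data from a model with
known ground truth, hand the estimator only the noisy observations, and
measure how well states and parameters are recovered.  Its users are
people fitting conductance-based neuron models (or other strongly
nonlinear ODEs) to voltage-clamp-style recordings where most state
variables are never measured.

## Methods

Four related estimators share one collocation backend:

* **Nudging** — integrate dx/dt = f(x, Θ) + U(y − Hx) forward with a
  fixed diagonal gain U on the observed components; the baseline for
  state synchronization with *known* parameters.
* **Constrained least squares** (= variational annealing) — minimize
  Σₙ‖Hx(tₙ) − y(tₙ)‖² over all states and parameters, enforcing the
  model dynamics as penalty constraints whose weight grows as 2^β,
  β = 0…24.
* **DSPE** — the same, but the constrained dynamics carry time-dependent
  gains U(tₙ) that are optimized jointly and penalized by Σₙ‖U(tₙ)‖²;
  the extra degrees of freedom smooth the nonconvex cost surface.
* **OC-DSPE** — the control is eliminated with the Pontryagin minimum
  principle, U_ll = −p_l(y − Hx)_l, which yields coupled *estimation
  dynamics* for the states x and conjugate momenta p,

      ẋ_d = f_d(x, Θ) − p_d([y − Hx]_d)²,
      ṗ_d = −(∂f/∂x_d)·p + [Hᵀ(y − Hx)]_d (1 − p_d²),

  enforced as annealed Hermite–Simpson constraints on the transformed
  cost Σ_l ½([y − Hx]_l)²(1 + p_l²).  The momenta magnitude serves as a
  built-in estimate-quality diagnostic.

Built-in models: the cyclic Lorenz96 benchmark (any D ≥ 4, forcing F)
and the Morris-Lecar neuron (V, w; 12 parameters; optional persistent-Na
channel for misspecification studies).  Models are stored symbolically
(sympy), so every constraint Jacobian — including the second-derivative
terms in the momenta equations — is exact and compiled to vectorized
numpy.  See `docs/methods.md` for the full formulation and numerical
choices.

## Worked example

Recover the Lorenz96 forcing from 4 of 10 noisy state traces:

```python
import numpy as np
import ocdspe as oc

model = oc.get_model("lorenz96", D=10, F=8.0)
grid = oc.TimeGrid(0.0, 0.016, 501)                 # t in [0, 8]
x0 = oc.transient_state(model, seed=100)            # settle on the attractor
truth = oc.integrate(model, x0, grid)
obs = oc.observe(truth, oc.ObservationOperator(10, (0, 3, 6, 9)),
                 sigma=1.0, seed=101)               # observe x1,x4,x7,x10

problem = oc.EstimationProblem(model, obs, method="dspe",
                               q=4, seed=42, max_iter=150)
result = problem.fit()
print(result.best.summary())
```

prints (seed-reproducible):

```
DSPE estimate of lorenz96 (10 states, 4 observed, N=501)
  measurement error E = 2046.28
  final residual norm = 0.000323
  parameter        estimate      bounds
  F                   8.01577   [1, 20]
```

`E` is the summed squared mismatch on the observed rows (the noise floor
here is ≈ 4·501·σ² ≈ 2000, so the best run fits the data down to the
noise), the residual norm measures how well the annealed estimate
satisfies the model dynamics, and `F = 8.016` recovers the generative
forcing 8.0 to 0.2 % — from a chaotic system with six never-observed
state variables.  Runs that end in a wrong basin announce themselves
with E several times larger; `result.summary()` lists all of them.

The same object fits neurons:

```python
ml = oc.get_model("morris_lecar")
# ... observe V under a 100 pA step, then
problem = oc.EstimationProblem(ml, obs, method="ocdspe",
                               fit_params=["g_fast", "g_slow", "g_leak"],
                               q=5, seed=7, max_iter=1500, maxcor=25,
                               bounds=oc.BoundsSpec(momenta_init=(0.0, 0.0)))
```

## Command line

`ocdspe simulate | nudge | estimate | predict | scan-cost | report | run`
— thin wrappers over the library; `run` executes a full twin experiment
from a JSON/TOML config and writes truth, observations, per-run results,
the best-run selection and a recovery report into a self-describing
output directory.

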