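"""Twin-experiment data synthesis.

Forward integration of the built-in models, stimulus construction, additive
Gaussian measurement noise on the observed components, and stochastic
("noisy input current") integration.  All stochastic steps are reproducible
from a seed; experiments split one master seed into independent streams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .models import ModelSpec, get_model

__all__ = [
    "TimeGrid",
    "Stimulus",
    "Trajectory",
    "ObservationOperator",
    "ObservationSet",
    "IntegrationError",
    "integrate",
    "observe",
    "integrate_process_noise",
    "make_chaotic_stimulus",
    "constant_stimulus",
    "transient_state",
]


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class TimeGrid:
    """Uniform grid t_n = t0 + n*dt, n = 0..N-1."""

    t0: float
    dt: float
    n: int

    def __post_init__(self):
        if self.dt <= 0 or self.n < 1:
            raise ValueError("TimeGrid requires dt > 0 and n >= 1")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.n - 1)

    @classmethod
    def from_span(cls, t0: float, t_end: float, dt: float) -> "TimeGrid":
        n = int(round((t_end - t0) / dt)) + 1
        return cls(t0, dt, n)


@dataclass
class Stimulus:
    """Injected current aligned to a grid, held piecewise-constant (ZOH)."""

    grid: TimeGrid
    values: np.ndarray
    kind: str = "custom"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n,):
            raise ValueError("stimulus length must match grid")

    def __call__(self, t):
        """Zero-order-hold lookup at arbitrary time(s)."""
        idx = np.clip(
            np.floor((np.asarray(t) - self.grid.t0) / self.grid.dt).astype(int),
            0,
            self.grid.n - 1,
        )
        return self.values[idx]


def constant_stimulus(grid: TimeGrid, amplitude: float) -> Stimulus:
    return Stimulus(grid, np.full(grid.n, float(amplitude)), kind="constant")


@dataclass
class Trajectory:
    grid: TimeGrid
    states: np.ndarray  # (D, N)
    state_names: list[str] | None = None

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=float)
        if self.states.ndim != 2 or self.states.shape[1] != self.grid.n:
            raise ValueError("states must be (D, N) on the grid")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("trajectory contains non-finite entries")

    @property
    def D(self) -> int:
        return self.states.shape[0]


@dataclass
class ObservationOperator:
    """Diagonal 0/1 measurement mask selecting L of D state components."""

    D: int
    observed_indices: tuple[int, ...]  # 0-based

    def __post_init__(self):
        idx = tuple(sorted(set(int(i) for i in self.observed_indices)))
        if idx and (idx[0] < 0 or idx[-1] >= self.D):
            raise ValueError("observed indices out of range")
        object.__setattr__(self, "observed_indices", idx)

    @property
    def L(self) -> int:
        return len(self.observed_indices)

    @property
    def H(self) -> np.ndarray:
        H = np.zeros((self.D, self.D))
        for i in self.observed_indices:
            H[i, i] = 1.0
        return H

    @property
    def mask(self) -> np.ndarray:
        m = np.zeros(self.D, dtype=bool)
        m[list(self.observed_indices)] = True
        return m

    def apply(self, states: np.ndarray) -> np.ndarray:
        out = np.zeros_like(states)
        out[list(self.observed_indices)] = states[list(self.observed_indices)]
        return out


@dataclass
class ObservationSet:
    """Noisy partial observations: y = Hx + N(0, sigma^2) on observed rows."""

    grid: TimeGrid
    y: np.ndarray  # (D, N), identically zero on unobserved rows
    op: ObservationOperator
    sigma: float
    seed: int | None = None
    stimulus: Stimulus | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        unobs = ~self.op.mask
        if np.any(self.y[unobs] != 0.0):
            raise ValueError("unobserved rows of y must be identically zero")

    @property
    def observed_y(self) -> np.ndarray:
        return self.y[list(self.op.observed_indices)]


def _stim_fun(stimulus, grid):
    if stimulus is None:
        return lambda t: 0.0
    if isinstance(stimulus, Stimulus):
        return stimulus
    if np.isscalar(stimulus):
        return lambda t: float(stimulus)
    return Stimulus(grid, stimulus)


def integrate(
    model: ModelSpec,
    x0,
    grid: TimeGrid,
    theta=None,
    stimulus=None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """High-accuracy deterministic solution sampled on ``grid`` (LSODA)."""
    theta = model.theta_or_default(theta)
    stim = _stim_fun(stimulus, grid)

    def f(t, x):
        return model.rhs(x, theta, stim=stim(t))

    sol = solve_ivp(
        f,
        (grid.t0, grid.t_end),
        np.asarray(x0, dtype=float),
        t_eval=grid.t,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        max_step=max(grid.dt, (grid.t_end - grid.t0) / 10) if grid.n > 1 else np.inf,
    )
    if not sol.success:
        raise IntegrationError(f"integration of {model.name} failed: {sol.message}")
    return Trajectory(grid, sol.y, state_names=model.state_names)


def integrate_process_noise(
    model: ModelSpec,
    x0,
    grid: TimeGrid,
    theta=None,
    stimulus=None,
    sd_noise: float = 0.0,
    seed: int | None = None,
) -> Trajectory:
    """Fixed-step (RK4) integration with a fresh N(0, SD^2) current draw
    added to the stimulus on every step of the grid.

    The draw is per step, not rescaled by sqrt(dt): the noisy current is held
    constant across each dt interval, which is the convention under which the
    stated SD values (10/50/100 pA at dt = 0.05 ms) are meaningful.
    """
    if sd_noise < 0:
        raise ValueError("sd_noise must be nonnegative")
    theta = model.theta_or_default(theta)
    stim = _stim_fun(stimulus, grid)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sd_noise, size=grid.n - 1) if sd_noise > 0 else np.zeros(grid.n - 1)

    x = np.empty((model.D, grid.n))
    x[:, 0] = np.asarray(x0, dtype=float)
    dt = grid.dt
    for k in range(grid.n - 1):
        tk = grid.t0 + k * dt
        I = float(np.asarray(stim(tk))) + noise[k]
        xk = x[:, k]
        k1 = model.rhs(xk, theta, stim=I)
        k2 = model.rhs(xk + 0.5 * dt * k1, theta, stim=I)
        k3 = model.rhs(xk + 0.5 * dt * k2, theta, stim=I)
        k4 = model.rhs(xk + dt * k3, theta, stim=I)
        x[:, k + 1] = xk + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
    return Trajectory(grid, x, state_names=model.state_names)


def observe(
    traj: Trajectory,
    op: ObservationOperator,
    sigma: float,
    seed: int | None = None,
    stimulus: Stimulus | None = None,
) -> ObservationSet:
    """y = Hx + independent N(0, sigma^2) on observed rows only."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    y = op.apply(traj.states).copy()
    if sigma > 0:
        idx = list(op.observed_indices)
        y[idx] += rng.normal(0.0, sigma, size=(len(idx), traj.grid.n))
    return ObservationSet(traj.grid, y, op, sigma, seed=seed, stimulus=stimulus)


def make_chaotic_stimulus(
    grid: TimeGrid,
    time_scale: float = 15.0,
    amplitude: float = 20.0,
    seed: int | None = None,
    transient: float = 20.0,
) -> Stimulus:
    """Chaotic injected current I(t) = amplitude * |x1(t / time_scale)|.

    ``x1`` is one component of a 10D Lorenz96 run at F = 8, started from a
    seeded random state and sampled after a discarded transient, so the
    stimulus persistently explores a wide current range while staying >= 0.
    """
    rng = np.random.default_rng(seed)
    l96 = get_model("lorenz96", D=10, F=8.0)
    x0 = rng.normal(0.0, 1.0, size=10)
    # settle onto the attractor before sampling
    pre = TimeGrid.from_span(0.0, transient, 0.05)
    x_on = integrate(l96, x0, pre).states[:, -1]
    inner = TimeGrid(0.0, grid.dt / time_scale, grid.n)
    traj = integrate(l96, x_on, inner)
    values = amplitude * np.abs(traj.states[0])
    return Stimulus(grid, values, kind="chaotic")


def transient_state(
    model: ModelSpec,
    theta=None,
    transient: float = 10.0,
    seed: int | None = None,
    stimulus_value: float = 0.0,
    x0=None,
) -> np.ndarray:
    """State on the attractor/limit cycle after discarding a transient.

    Starts from a seeded random state (standard normal, scaled into the model
    state box) unless ``x0`` is given, integrates for ``transient`` time
    units under a constant stimulus, and returns the final state.
    """
    rng = np.random.default_rng(seed)
    if x0 is None:
        lo, hi = model.state_bounds[:, 0], model.state_bounds[:, 1]
        lo = np.where(np.isfinite(lo), lo, -1.0)
        hi = np.where(np.isfinite(hi), hi, 1.0)
        x0 = rng.uniform(lo + 0.25 * (hi - lo), hi - 0.25 * (hi - lo))
    grid = TimeGrid.from_span(0.0, transient, transient / 400)
    return integrate(model, x0, grid, theta=theta, stimulus=stimulus_value).states[:, -1]
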