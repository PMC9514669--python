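"""File formats, experiment configuration, and the full-experiment driver.

Time series travel as CSV (header row, time first column); results and
reports as JSON; grids, seeds, noise levels and masks in JSON sidecars so
every artifact is self-describing.  A single master seed is split into
independent streams for (initial state, measurement noise, process noise,
multistart initializations).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimators import (
    AnnealingSchedule,
    BoundsSpec,
    EstimationProblem,
    MultistartResult,
    predict,
)
from .evaluate import RecoveryReport
from .models import get_model
from .simulate import (
    ObservationOperator,
    ObservationSet,
    Stimulus,
    TimeGrid,
    Trajectory,
    constant_stimulus,
    integrate,
    integrate_process_noise,
    make_chaotic_stimulus,
    observe,
    transient_state,
)

log = logging.getLogger("ocdspe")

__all__ = [
    "ExperimentConfig",
    "ConfigError",
    "run_experiment",
    "write_trajectory",
    "read_trajectory",
    "write_observations",
    "read_observations",
    "write_result",
]


class ConfigError(ValueError):
    """Invalid experiment configuration; message carries the field path."""


# ---------------------------------------------------------------------------
# CSV / JSON round-trips
# ---------------------------------------------------------------------------

def write_trajectory(path, traj: Trajectory, meta: dict | None = None) -> None:
    names = traj.state_names or [f"x{i+1}" for i in range(traj.D)]
    df = pd.DataFrame({"time": traj.grid.t})
    for i, n in enumerate(names):
        df[n] = traj.states[i]
    df.to_csv(path, index=False)
    side = {"t0": traj.grid.t0, "dt": traj.grid.dt, "n": traj.grid.n}
    side.update(meta or {})
    Path(str(path) + ".json").write_text(json.dumps(side, indent=2))


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    t = df["time"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    grid = TimeGrid(float(t[0]), dt, len(t))
    names = [c for c in df.columns if c != "time"]
    return Trajectory(grid, df[names].to_numpy().T, state_names=names)


def write_observations(path, obs: ObservationSet, state_names=None) -> None:
    names = state_names or [f"x{i+1}" for i in range(obs.y.shape[0])]
    df = pd.DataFrame({"time": obs.grid.t})
    for i in obs.op.observed_indices:
        df[names[i]] = obs.y[i]
    df.to_csv(path, index=False)
    side = {
        "t0": obs.grid.t0,
        "dt": obs.grid.dt,
        "n": obs.grid.n,
        "sigma": obs.sigma,
        "seed": obs.seed,
        "observed_indices": list(obs.op.observed_indices),
        "D": obs.op.D,
        "state_names": list(names),
    }
    if obs.stimulus is not None:
        side["stimulus"] = list(map(float, obs.stimulus.values))
    Path(str(path) + ".json").write_text(json.dumps(side))


def read_observations(path) -> ObservationSet:
    df = pd.read_csv(path)
    side = json.loads(Path(str(path) + ".json").read_text())
    grid = TimeGrid(side["t0"], side["dt"], side["n"])
    D = side["D"]
    names = side["state_names"]
    y = np.zeros((D, grid.n))
    for i in side["observed_indices"]:
        y[i] = df[names[i]].to_numpy()
    op = ObservationOperator(D, tuple(side["observed_indices"]))
    stim = None
    if "stimulus" in side:
        stim = Stimulus(grid, np.asarray(side["stimulus"]))
    return ObservationSet(grid, y, op, side["sigma"], seed=side.get("seed"), stimulus=stim)


def write_result(path, result, truth: dict | None = None) -> None:
    """EstimateResult -> JSON (parameters, E, residuals, per-beta trace)."""
    payload = {
        "method": result.problem.method,
        "model": result.problem.model.name,
        "theta_hat": result.theta_hat,
        "E": result.E,
        "residual_norm": result.residuals.norm,
        "converged": result.converged,
        "init_seed": result.init_seed,
        "trace": [
            {k: float(v) if isinstance(v, (int, float, np.floating)) else v for k, v in t.items()}
            for t in result.trace
        ],
    }
    if result.p_hat is not None:
        payload["mean_abs_p"] = result.mean_abs_p
    if truth:
        payload["truth"] = truth
    Path(path).write_text(json.dumps(payload, indent=2))


# ---------------------------------------------------------------------------
# experiment configuration
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Declarative description of one twin experiment.

    Loadable from JSON or TOML; every stochastic step derives from ``seed``.
    """

    model: str = "lorenz96"
    model_kwargs: dict = field(default_factory=dict)
    t0: float = 0.0
    dt: float = 0.016
    n: int = 501
    transient: float = 10.0
    stimulus: str | None = None          # none | "constant" | "chaotic"
    stimulus_amplitude: float = 100.0
    process_noise_sd: float = 0.0
    observed: tuple = (0, 3)             # 0-based state indices
    sigma: float = 1.0
    method: str = "ocdspe"
    fit_params: list | None = None
    q: int = 2
    beta_max: int = 24
    lambda0: float = 1.0
    alpha: float = 2.0
    max_iter: int = 1000
    maxcor: int = 10
    seed: int = 0
    out_dir: str = "ocdspe_run"

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            raw = tomllib.loads(path.read_text())
        else:
            raw = json.loads(path.read_text())
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config fields: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.dt <= 0:
            raise ConfigError("dt: must be positive")
        if self.n < 2:
            raise ConfigError("n: need at least 2 timepoints")
        if self.method not in ("lsq", "dspe", "ocdspe"):
            raise ConfigError(f"method: unknown method {self.method!r}")
        if self.q < 1:
            raise ConfigError("q: need at least one initialization")
        if self.sigma < 0:
            raise ConfigError("sigma: must be nonnegative")

    def to_json(self) -> str:
        d = asdict(self)
        d["observed"] = list(d["observed"])
        return json.dumps(d, indent=2)


def run_experiment(config: ExperimentConfig, out_dir=None) -> dict:
    """Generate twin data per config, estimate, select best, write artifacts.

    Returns a small summary dict; files land under ``config.out_dir``:
    truth.csv, observations.csv, run_<i>.json, best.json, recovery.json,
    config.json, and experiment.log.
    """
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    fh = logging.FileHandler(out / "experiment.log", mode="w")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    try:
        model = get_model(config.model, **config.model_kwargs)
        truth = {n: p.value for n, p in model.param_set.items()}
        grid = TimeGrid(config.t0, config.dt, config.n)
        ss = np.random.SeedSequence(config.seed).spawn(4)
        seed_x0, seed_meas, seed_proc, seed_fit = (int(s.generate_state(1)[0] % 2**31) for s in ss)

        stim = None
        if config.stimulus == "constant":
            stim = constant_stimulus(grid, config.stimulus_amplitude)
        elif config.stimulus == "chaotic":
            stim = make_chaotic_stimulus(grid, seed=seed_x0)
        elif config.stimulus is not None:
            raise ConfigError(f"stimulus: unknown kind {config.stimulus!r}")

        sv = float(stim.values[0]) if stim is not None else 0.0
        x0 = transient_state(model, transient=config.transient, seed=seed_x0, stimulus_value=sv)
        if config.process_noise_sd > 0:
            traj = integrate_process_noise(
                model, x0, grid, stimulus=stim, sd_noise=config.process_noise_sd, seed=seed_proc
            )
        else:
            traj = integrate(model, x0, grid, stimulus=stim)
        op = ObservationOperator(model.D, tuple(config.observed))
        obs = observe(traj, op, config.sigma, seed=seed_meas, stimulus=stim)

        write_trajectory(out / "truth.csv", traj, meta={"theta": truth, "seed": config.seed})
        write_observations(out / "observations.csv", obs, state_names=model.state_names)

        schedule = AnnealingSchedule(
            lambda0=config.lambda0, alpha=config.alpha, beta_max=config.beta_max
        )
        problem = EstimationProblem(
            model,
            obs,
            method=config.method,
            fit_params=config.fit_params,
            schedule=schedule,
            q=config.q,
            seed=seed_fit,
            max_iter=config.max_iter,
            maxcor=config.maxcor,
        )
        log.info("experiment: model=%s method=%s q=%d seed=%d", config.model, config.method, config.q, config.seed)
        ms: MultistartResult = problem.fit()
        for i, r in enumerate(ms.runs):
            write_result(out / f"run_{i}.json", r, truth=truth)
            for tr in r.trace:
                log.info(
                    "run %d beta=%d cost=%.6g resid=%.3g nit=%d status=%d",
                    i, tr["beta"], tr["cost"], tr["resid_norm"], tr["nit"], tr["status"],
                )
        write_result(out / "best.json", ms.best, truth=truth)
        report = RecoveryReport.from_multistart(ms, truth)
        (out / "recovery.json").write_text(report.table.to_json(orient="records"))
        (out / "config.json").write_text(config.to_json())
        log.info("best run %d: E=%.6g", ms.best_index, ms.best.E)
        return {
            "best_index": ms.best_index,
            "best_E": ms.best.E,
            "theta_hat": ms.best.theta_hat,
            "truth": truth,
            "out_dir": str(out),
        }
    finally:
        log.removeHandler(fh)
        fh.close()
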