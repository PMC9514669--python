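"""Built-in dynamical systems: Lorenz96 and the Morris-Lecar neuron.

Each model is a :class:`ModelSpec` — a named ODE system holding sympy
expressions for its vector field, a registry of parameters with bounds and
roles, and compiled numeric ``rhs`` / ``jac_state`` callables.  The symbolic
form is what lets the estimators derive exact derivatives of every
discretized constraint.

Parameter roles tag how a parameter enters the physics:

* ``conductance`` — linear channel conductances (the Fig.-4-style restricted
  fits optimize exactly these),
* ``reversal-potential`` — Nernst potentials, sign-carrying,
* ``kinetic`` — gating time scales and half-activation constants,
* ``forcing`` — external forcing (Lorenz96 ``F``),
* ``capacitance`` — membrane capacitance.

Units for the neuron are the consistent mV / ms / pA system in which the
ground-truth numbers are quoted; no conversion is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import sympy as sp

from ._compile import CompiledField

__all__ = [
    "Parameter",
    "ParameterSet",
    "ModelSpec",
    "lorenz96_rhs",
    "ml_gates",
    "ml_rhs",
    "ml_nap_rhs",
    "get_model",
    "list_models",
    "register_model",
]


class InvalidModelError(ValueError):
    """Raised for structurally invalid model definitions."""


class InvalidParameterError(ValueError):
    """Raised when a parameter value makes the model ill-defined."""


@dataclass
class Parameter:
    value: float
    lower: float
    upper: float
    role: str = "kinetic"

    def __post_init__(self):
        if not self.lower <= self.value <= self.upper:
            raise InvalidParameterError(
                f"value {self.value} outside bounds [{self.lower}, {self.upper}]"
            )


class ParameterSet(dict):
    """Ordered name -> :class:`Parameter` map (insertion-ordered dict)."""

    @property
    def names(self) -> list[str]:
        return list(self.keys())

    @property
    def values_array(self) -> np.ndarray:
        return np.array([p.value for p in self.values()], dtype=float)

    @property
    def bounds_array(self) -> np.ndarray:
        return np.array([(p.lower, p.upper) for p in self.values()], dtype=float)

    def by_role(self, role: str) -> list[str]:
        return [k for k, p in self.items() if p.role == role]

    def with_values(self, **updates) -> "ParameterSet":
        out = ParameterSet()
        for k, p in self.items():
            v = updates.pop(k, p.value)
            out[k] = Parameter(v, p.lower, p.upper, p.role)
        if updates:
            raise KeyError(f"unknown parameters: {sorted(updates)}")
        return out


@dataclass
class ModelSpec:
    """A named ODE system dx/dt = f(x, theta, I_stim(t))."""

    name: str
    state_names: list[str]
    state_syms: list[sp.Symbol]
    param_set: ParameterSet
    param_syms: list[sp.Symbol]
    exprs: list[sp.Expr]
    stim_sym: sp.Symbol | None = None
    state_bounds: np.ndarray | None = None  # (D, 2) default search box
    state_residual_scales: np.ndarray | None = None     # R_i for state equations
    momentum_residual_scales: np.ndarray | None = None  # R_i for momenta equations
    _field: CompiledField = field(init=False, repr=False, default=None)

    def __post_init__(self):
        if len(self.exprs) != len(self.state_syms):
            raise InvalidModelError("rhs length must equal state dimension")
        if self.state_residual_scales is None:
            self.state_residual_scales = np.ones(len(self.state_syms))
        if self.momentum_residual_scales is None:
            self.momentum_residual_scales = np.ones(len(self.state_syms))
        data = [self.stim_sym] if self.stim_sym is not None else []
        self._field = CompiledField(
            self.state_syms, self.param_syms, [], data, self.exprs
        )
        if self.state_bounds is None:
            self.state_bounds = np.tile([-np.inf, np.inf], (self.D, 1))

    @property
    def D(self) -> int:
        return len(self.state_syms)

    @property
    def parameters(self) -> ParameterSet:
        return self.param_set

    def theta_or_default(self, theta=None) -> np.ndarray:
        if theta is None:
            return self.param_set.values_array
        return np.asarray(theta, dtype=float)

    def _data(self, stim, ncols):
        if self.stim_sym is None:
            return None
        return np.broadcast_to(np.asarray(stim, dtype=float), (1, ncols))

    def rhs(self, x, theta=None, stim=0.0) -> np.ndarray:
        """Vector field at states ``x`` (shape (D,) or (D, N))."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x2 = np.atleast_2d(x.reshape(self.D, -1))
        out = self._field.f(x2, self.theta_or_default(theta), data=self._data(stim, x2.shape[1]))
        return out[:, 0] if single else out

    def jac_state(self, x, theta=None, stim=0.0) -> np.ndarray:
        """Analytic Jacobian d f / d x; (D, D) single state, else (N, D, D)."""
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x2 = np.atleast_2d(x.reshape(self.D, -1))
        out = self._field.jac_z(x2, self.theta_or_default(theta), data=self._data(stim, x2.shape[1]))
        return out[:, :, 0] if single else np.moveaxis(out, 2, 0)

    def jac_params(self, x, theta=None, stim=0.0) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        single = x.ndim == 1
        x2 = np.atleast_2d(x.reshape(self.D, -1))
        out = self._field.jac_theta(x2, self.theta_or_default(theta), data=self._data(stim, x2.shape[1]))
        return out[:, :, 0] if single else np.moveaxis(out, 2, 0)


# ---------------------------------------------------------------------------
# Lorenz96
# ---------------------------------------------------------------------------

def lorenz96_rhs(x, F):
    """Cyclic Lorenz96 field: dx_d/dt = (x_{d+1} - x_{d-2}) x_{d-1} - x_d + F."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] < 4:
        raise InvalidModelError("Lorenz96 requires dimension D >= 4")
    return (np.roll(x, -1, axis=0) - np.roll(x, 2, axis=0)) * np.roll(x, 1, axis=0) - x + F


def _build_lorenz96(D=10, F=8.0, F_bounds=(1.0, 20.0)):
    if D < 4:
        raise InvalidModelError("Lorenz96 requires dimension D >= 4")
    xs = sp.symbols(f"x1:{D + 1}")
    Fs = sp.Symbol("F")
    exprs = [
        (xs[(d + 1) % D] - xs[(d - 2) % D]) * xs[(d - 1) % D] - xs[d] + Fs
        for d in range(D)
    ]
    params = ParameterSet(F=Parameter(F, *F_bounds, role="forcing"))
    return ModelSpec(
        name=f"lorenz96_{D}d" if D != 10 else "lorenz96",
        state_names=[f"x{d + 1}" for d in range(D)],
        state_syms=list(xs),
        param_set=params,
        param_syms=[Fs],
        exprs=exprs,
        state_bounds=np.tile([-15.0, 15.0], (D, 1)),
        state_residual_scales=np.full(D, 1e-4),
        momentum_residual_scales=np.full(D, 1e-4),
    )


# ---------------------------------------------------------------------------
# Morris-Lecar (K + Na, optionally + persistent Na)
# ---------------------------------------------------------------------------

#: ground-truth parameter values for the two-channel (K+Na) neuron
ML_TRUE = {
    "C": 2.5,
    "g_fast": 20.0,
    "g_slow": 15.0,
    "g_leak": 2.0,
    "E_Na": 50.0,
    "E_K": -100.0,
    "E_leak": -70.0,
    "phi_w": 0.12,
    "beta_w": 0.0,
    "beta_m": -1.2,
    "gamma_m": 18.0,
    "gamma_w": 10.0,
}

#: extra persistent-sodium channel parameters
ML_NAP_TRUE = {"g_NaP": 3.0, "E_NaP": 50.0}

_POS = (0.01, 200.0)       # positive parameters: span two orders of magnitude
_SIGNED = (-200.0, 200.0)  # reversal potentials and half-activation voltages

_ML_ROLES = {
    "C": ("capacitance", _POS),
    "g_fast": ("conductance", _POS),
    "g_slow": ("conductance", _POS),
    "g_leak": ("conductance", _POS),
    "E_Na": ("reversal-potential", _SIGNED),
    "E_K": ("reversal-potential", _SIGNED),
    "E_leak": ("reversal-potential", _SIGNED),
    "phi_w": ("kinetic", _POS),
    "beta_w": ("kinetic", _SIGNED),
    "beta_m": ("kinetic", _SIGNED),
    "gamma_m": ("kinetic", _POS),
    "gamma_w": ("kinetic", _POS),
    "g_NaP": ("conductance", _POS),
    "E_NaP": ("reversal-potential", _SIGNED),
}


def _theta_dict(theta):
    if isinstance(theta, ParameterSet):
        return {k: p.value for k, p in theta.items()}
    return dict(theta)


def ml_gates(V, theta):
    """Steady-state activations and gating time constant.

    Returns ``(w_inf, m_inf, tau_w)`` with w_inf(V) = (1 + tanh((V-beta_w)/
    gamma_w))/2, m_inf analogous with (beta_m, gamma_m), and
    tau_w(V) = 1/cosh((V-beta_w)/(2 gamma_w)).
    """
    th = _theta_dict(theta)
    if th["gamma_w"] == 0 or th["gamma_m"] == 0:
        raise InvalidParameterError("gamma_w and gamma_m must be nonzero")
    V = np.asarray(V, dtype=float)
    w_inf = 0.5 * (1 + np.tanh((V - th["beta_w"]) / th["gamma_w"]))
    m_inf = 0.5 * (1 + np.tanh((V - th["beta_m"]) / th["gamma_m"]))
    tau_w = 1.0 / np.cosh((V - th["beta_w"]) / (2 * th["gamma_w"]))
    return w_inf, m_inf, tau_w


def ml_rhs(state, theta, I_stim=0.0):
    """Two-channel Morris-Lecar field: state = (V, w), currents in pA."""
    th = _theta_dict(theta)
    if th["C"] <= 0:
        raise InvalidParameterError("capacitance C must be positive")
    V, w = np.asarray(state, dtype=float)
    w_inf, m_inf, tau_w = ml_gates(V, th)
    I_ion = (
        -th["g_fast"] * m_inf * (V - th["E_Na"])
        - th["g_slow"] * w * (V - th["E_K"])
        - th["g_leak"] * (V - th["E_leak"])
    )
    dV = (I_ion + I_stim) / th["C"]
    dw = th["phi_w"] * (w_inf - w) / tau_w
    return np.array([dV, dw])


def ml_nap_rhs(state, theta, I_stim=0.0):
    """Morris-Lecar field with an added persistent-Na current."""
    th = _theta_dict(theta)
    V, w = np.asarray(state, dtype=float)
    _, m_inf, _ = ml_gates(V, th)
    base = ml_rhs(state, {k: v for k, v in th.items() if k in ML_TRUE}, I_stim)
    extra = -th["g_NaP"] * m_inf * (V - th["E_NaP"]) / th["C"]
    return base + np.array([extra, 0.0 * extra])


def _build_morris_lecar(nap=False, **overrides):
    truth = dict(ML_TRUE)
    if nap:
        truth.update(ML_NAP_TRUE)
    truth.update(overrides)
    names = list(truth)
    params = ParameterSet(
        {n: Parameter(truth[n], *_ML_ROLES[n][1], role=_ML_ROLES[n][0]) for n in names}
    )
    V, w = sp.symbols("V w")
    I = sp.Symbol("I_stim")
    syms = {n: sp.Symbol(n) for n in names}
    w_inf = (1 + sp.tanh((V - syms["beta_w"]) / syms["gamma_w"])) / 2
    m_inf = (1 + sp.tanh((V - syms["beta_m"]) / syms["gamma_m"])) / 2
    tau_w = 1 / sp.cosh((V - syms["beta_w"]) / (2 * syms["gamma_w"]))
    I_ion = (
        -syms["g_fast"] * m_inf * (V - syms["E_Na"])
        - syms["g_slow"] * w * (V - syms["E_K"])
        - syms["g_leak"] * (V - syms["E_leak"])
    )
    if nap:
        I_ion = I_ion - syms["g_NaP"] * m_inf * (V - syms["E_NaP"])
    dV = (I_ion + I) / syms["C"]
    dw = syms["phi_w"] * (w_inf - w) / tau_w
    return ModelSpec(
        name="morris_lecar_nap" if nap else "morris_lecar",
        state_names=["V", "w"],
        state_syms=[V, w],
        param_set=params,
        param_syms=[syms[n] for n in names],
        exprs=[dV, dw],
        stim_sym=I,
        state_bounds=np.array([[-100.0, 100.0], [0.0, 1.0]]),
        state_residual_scales=np.array([1e-4, 1.0]),
        momentum_residual_scales=np.array([1.0, 1.0]),
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_REGISTRY: dict[str, Callable[..., ModelSpec]] = {
    "lorenz96": _build_lorenz96,
    "morris_lecar": lambda **kw: _build_morris_lecar(nap=False, **kw),
    "morris_lecar_nap": lambda **kw: _build_morris_lecar(nap=True, **kw),
}


def register_model(name: str, builder: Callable[..., ModelSpec]) -> None:
    """Register a custom model builder under ``name``."""
    _REGISTRY[name] = builder


def list_models() -> list[str]:
    return sorted(_REGISTRY)


def get_model(name: str, **kwargs) -> ModelSpec:
    """Build a registered model, optionally overriding parameter values.

    ``get_model("lorenz96", D=5, F=8.0)`` or
    ``get_model("morris_lecar", g_slow=10.0)``.
    """
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise InvalidModelError(
            f"unknown model {name!r}; available: {list_models()}"
        ) from None
    return builder(**kwargs)
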