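import numpy as np
import pytest

import ocdspe as oc


@pytest.fixture(scope="session")
def l96_5d():
    return oc.get_model("lorenz96", D=5, F=8.0)


@pytest.fixture(scope="session")
def l96_10d():
    return oc.get_model("lorenz96", D=10, F=8.0)


@pytest.fixture(scope="session")
def ml():
    return oc.get_model("morris_lecar")


@pytest.fixture(scope="session")
def ml_nap():
    return oc.get_model("morris_lecar_nap")


@pytest.fixture(scope="session")
def lin1d():
    """Fully observed 1D linear decay model xdot = -a x, a = 1.3."""
    import sympy as sp

    from ocdspe.models import ModelSpec, Parameter, ParameterSet

    x = sp.Symbol("x1")
    a = sp.Symbol("a")
    return ModelSpec(
        name="lin1d",
        state_names=["x1"],
        state_syms=[x],
        param_set=ParameterSet(a=Parameter(1.3, 0.1, 5.0)),
        param_syms=[a],
        exprs=[-a * x],
        state_bounds=np.array([[-5.0, 5.0]]),
    )


@pytest.fixture(scope="session")
def l96_5d_twin(l96_5d):
    """Short noisy 5D Lorenz96 twin data set, x1 and x4 observed."""
    grid = oc.TimeGrid(0.0, 0.016, 126)
    x0 = oc.transient_state(l96_5d, seed=10)
    traj = oc.integrate(l96_5d, x0, grid)
    obs = oc.observe(traj, oc.ObservationOperator(5, (0, 3)), 1.0, seed=11)
    return traj, obs


@pytest.fixture(scope="session")
def ml_step_twin(ml):
    """Morris-Lecar twin data under a 100 pA step, V observed, sigma = 2 mV."""
    grid = oc.TimeGrid(0.0, 0.05, 2001)
    stim = oc.constant_stimulus(grid, 100.0)
    x0 = oc.transient_state(
        ml, seed=300, stimulus_value=100.0, x0=np.array([-70.0, 0.0]), transient=50.0
    )
    traj = oc.integrate(ml, x0, grid, stimulus=stim)
    obs = oc.observe(traj, oc.ObservationOperator(2, (0,)), 2.0, seed=301, stimulus=stim)
    return traj, obs
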