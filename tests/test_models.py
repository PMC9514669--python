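"""Model definitions: vector fields, gating functions, analytic Jacobians."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ocdspe as oc
from ocdspe.models import (
    ML_NAP_TRUE,
    ML_TRUE,
    InvalidModelError,
    InvalidParameterError,
    lorenz96_rhs,
    ml_gates,
    ml_nap_rhs,
    ml_rhs,
)


class TestLorenz96:
    def test_constant_fixed_point(self):
        assert np.allclose(lorenz96_rhs(np.full(5, 8.0), 8.0), 0.0)

    def test_forcing_only_at_origin(self):
        assert np.allclose(lorenz96_rhs(np.zeros(7), 8.0), 8.0)

    def test_hand_evaluated_component(self):
        # d=1 with x=(1,2,3,4,5), F=0: (x2-x4)*x5 - x1 = (2-4)*5 - 1 = -11
        out = lorenz96_rhs(np.array([1.0, 2, 3, 4, 5]), 0.0)
        assert out[0] == pytest.approx(-11.0)

    def test_low_dimension_rejected(self):
        with pytest.raises(InvalidModelError):
            lorenz96_rhs(np.ones(3), 8.0)
        with pytest.raises(InvalidModelError):
            oc.get_model("lorenz96", D=3)

    @given(shift=st.integers(min_value=1, max_value=9), seed=st.integers(0, 100))
    @settings(max_examples=25, deadline=None)
    def test_cyclic_equivariance(self, shift, seed):
        x = np.random.default_rng(seed).normal(0, 5, size=10)
        lhs = lorenz96_rhs(np.roll(x, shift), 8.0)
        rhs = np.roll(lorenz96_rhs(x, 8.0), shift)
        assert np.allclose(lhs, rhs)

    def test_jacobian_diagonal_is_minus_one(self, l96_10d):
        x = np.random.default_rng(0).normal(0, 5, size=10)
        J = l96_10d.jac_state(x)
        assert np.allclose(np.diag(J), -1.0)

    def test_spec_matches_standalone_rhs(self, l96_5d):
        x = np.random.default_rng(1).normal(0, 5, size=5)
        assert np.allclose(l96_5d.rhs(x), lorenz96_rhs(x, 8.0))


class TestMorrisLecarGates:
    def test_half_activation(self):
        w_inf, m_inf, tau_w = ml_gates(ML_TRUE["beta_m"], ML_TRUE)
        assert m_inf == pytest.approx(0.5)
        w_inf, m_inf, tau_w = ml_gates(ML_TRUE["beta_w"], ML_TRUE)
        assert tau_w == pytest.approx(1.0)
        assert w_inf == pytest.approx(0.5)

    def test_saturation(self):
        w_inf, m_inf, tau_w = ml_gates(1e4, ML_TRUE)
        assert w_inf == pytest.approx(1.0)
        assert m_inf == pytest.approx(1.0)

    @given(v=st.floats(-120, 120))
    @settings(max_examples=50, deadline=None)
    def test_ranges(self, v):
        w_inf, m_inf, tau_w = ml_gates(v, ML_TRUE)
        assert 0.0 < w_inf < 1.0 or np.isclose(w_inf, [0, 1]).any()
        assert tau_w > 0

    def test_zero_gamma_rejected(self):
        bad = dict(ML_TRUE, gamma_w=0.0)
        with pytest.raises(InvalidParameterError):
            ml_gates(0.0, bad)


class TestMorrisLecarRHS:
    def test_gating_equilibrium(self):
        V = -20.0
        w_inf, _, _ = ml_gates(V, ML_TRUE)
        dx = ml_rhs(np.array([V, w_inf]), ML_TRUE, 0.0)
        assert dx[1] == pytest.approx(0.0, abs=1e-12)

    def test_all_currents_vanish(self):
        th = dict(ML_TRUE, g_leak=0.0)
        dx = ml_rhs(np.array([th["E_Na"], 0.0]), th, 0.0)
        # fast-channel driving force zero at E_Na, slow gate closed, no leak
        assert dx[0] == pytest.approx(0.0, abs=1e-12)

    def test_resting_point_near_leak_reversal(self, ml):
        """With no stimulus the fixed point sits just above E_leak: the slow
        K-like current is shut (w_inf ~ 0 there) and the residual fast
        inward current depolarizes the leak equilibrium by under 1 mV."""
        from scipy.optimize import brentq

        def dv(V):
            w_inf, _, _ = ml_gates(V, ML_TRUE)
            return ml_rhs(np.array([V, w_inf]), ML_TRUE, 0.0)[0]

        v_rest = brentq(dv, -99.0, -40.0)
        assert ML_TRUE["E_K"] < v_rest < ML_TRUE["E_Na"]
        assert ML_TRUE["E_leak"] < v_rest < ML_TRUE["E_leak"] + 1.0

    def test_dwdt_linear_coefficient(self, ml):
        # d(dw/dt)/dw = -phi_w / tau_w(V)
        V = -33.0
        _, _, tau_w = ml_gates(V, ML_TRUE)
        J = ml.jac_state(np.array([V, 0.4]))
        assert J[1, 1] == pytest.approx(-ML_TRUE["phi_w"] / tau_w)


class TestPersistentSodium:
    def test_zero_conductance_reduces_to_base(self):
        th = {**ML_TRUE, **ML_NAP_TRUE, "g_NaP": 0.0}
        s = np.array([-25.0, 0.3])
        assert np.allclose(ml_nap_rhs(s, th, 55.0), ml_rhs(s, ML_TRUE, 55.0))

    def test_all_currents_vanish(self):
        th = dict(ML_TRUE, **ML_NAP_TRUE, g_leak=0.0)
        dx = ml_nap_rhs(np.array([50.0, 0.0]), th, 0.0)  # V = E_Na = E_NaP
        assert dx[0] == pytest.approx(0.0, abs=1e-12)

    def test_algebraic_difference(self):
        th = dict(ML_TRUE, **ML_NAP_TRUE)
        s = np.array([-10.0, 0.2])
        _, m_inf, _ = ml_gates(s[0], th)
        expected = -th["g_NaP"] * m_inf * (s[0] - th["E_NaP"]) / th["C"]
        diff = ml_nap_rhs(s, th, 30.0)[0] - ml_rhs(s, ML_TRUE, 30.0)[0]
        assert diff == pytest.approx(expected)


@pytest.mark.parametrize("name", ["lorenz96", "morris_lecar", "morris_lecar_nap"])
def test_jacobian_matches_finite_differences(name):
    """Analytic state Jacobian agrees with central differences (rtol 1e-5)."""
    model = oc.get_model(name)
    rng = np.random.default_rng(42)
    for _ in range(5):
        if name == "lorenz96":
            x = rng.normal(0, 5, size=model.D)
            stim = 0.0
        else:
            x = np.array([rng.uniform(-80, 30), rng.uniform(0.05, 0.95)])
            stim = rng.uniform(0, 100)
        J = model.jac_state(x, stim=stim)
        eps = 1e-5
        for j in range(model.D):
            e = np.zeros(model.D)
            e[j] = eps
            fd = (model.rhs(x + e, stim=stim) - model.rhs(x - e, stim=stim)) / (2 * eps)
            assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-7)


def test_parameter_registry_roles(ml_nap):
    assert set(ml_nap.param_set.by_role("conductance")) == {
        "g_fast", "g_slow", "g_leak", "g_NaP",
    }
    assert ml_nap.param_set["E_K"].lower < 0  # reversal potentials keep signed bounds
    with pytest.raises(InvalidParameterError):
        oc.Parameter(300.0, 0.01, 200.0)


def test_registry_lookup_and_overrides():
    m = oc.get_model("morris_lecar", g_slow=10.0)
    assert m.param_set["g_slow"].value == 10.0
    with pytest.raises(InvalidModelError):
        oc.get_model("not_a_model")
    assert "lorenz96" in oc.list_models()
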