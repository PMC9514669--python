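"""Cost functions, estimation dynamics, annealing driver, multistart."""

import numpy as np
import pytest

import ocdspe as oc
from ocdspe.estimators import build_ocdspe_field


@pytest.fixture(scope="module")
def lin_twin(lin1d):
    grid = oc.TimeGrid(0.0, 0.05, 41)
    traj = oc.integrate(lin1d, np.array([2.0]), grid)
    obs = oc.observe(traj, oc.ObservationOperator(1, (0,)), 0.0)
    return traj, obs


class TestCostFunctions:
    def test_lsq(self, l96_5d_twin):
        truth, obs = l96_5d_twin
        assert oc.cost_lsq(obs.y, obs) == 0.0
        x = obs.y.copy()
        x[0] += 3.0  # one observed row offset by c at all N points
        assert oc.cost_lsq(x, obs) == pytest.approx(obs.grid.n * 9.0)

    def test_dspe_reduces_to_lsq(self, l96_5d_twin):
        truth, obs = l96_5d_twin
        u = np.zeros((2, obs.grid.n))
        assert oc.cost_dspe(truth.states, u, obs) == oc.cost_lsq(truth.states, obs)
        u[1, 7] = 4.0
        assert oc.cost_dspe(obs.y, u, obs) == pytest.approx(16.0)

    def test_ocdspe(self, l96_5d_twin):
        truth, obs = l96_5d_twin
        p = np.zeros_like(truth.states)
        assert oc.cost_ocdspe(truth.states, p, obs) == pytest.approx(
            0.5 * oc.cost_lsq(truth.states, obs)
        )
        assert oc.cost_ocdspe(obs.y, np.ones_like(p), obs) == 0.0
        # single observed point with y - x = 2 and p = 3 -> 0.5*4*10 = 20
        x = obs.y.copy()
        x[0, 0] -= 2.0
        p = np.zeros_like(x)
        p[0, 0] = 3.0
        single = oc.cost_ocdspe(x, p, obs) - oc.cost_ocdspe(x, np.zeros_like(p), obs)
        assert single + 0.5 * 4 == pytest.approx(20.0)

    def test_optimal_control(self):
        assert oc.optimal_control(0.0, 1.0, 5.0) == 0.0
        assert oc.optimal_control(2.0, 3.0, 3.0) == 0.0
        assert oc.optimal_control(2.0, 0.0, 3.0) == -6.0
        with pytest.raises(ValueError):
            oc.optimal_control(1.0, 0.0, 1.0, observed=False)


class TestEstimationDynamics:
    def test_uncontrolled_limit(self, l96_5d):
        x = np.random.default_rng(0).normal(0, 3, size=5)
        y = np.zeros(5)
        y[[0, 3]] = x[[0, 3]]  # y = Hx on observed rows
        xdot, pdot = oc.estimation_dynamics(l96_5d, x, np.zeros(5), y=y)
        assert np.allclose(xdot, l96_5d.rhs(x))
        assert np.allclose(pdot, 0.0)

    def test_unobserved_components_follow_model(self, l96_5d):
        rng = np.random.default_rng(1)
        x, p = rng.normal(0, 3, size=(2, 5))
        y = np.zeros(5)
        y[[0, 3]] = rng.normal(0, 3, size=2)
        xdot, _ = oc.estimation_dynamics(l96_5d, x, p, y=y)
        f = l96_5d.rhs(x)
        assert np.allclose(xdot[[1, 2, 4]], f[[1, 2, 4]])

    def test_hand_evaluated_linear_model(self, lin1d):
        # f = -a x, observed, at (x, p, y) = (1, 1, 2), a = 1.3:
        # xdot = -a - (2-1)^2 = -a - 1 ; pdot = a*1 + (2-1)*(1-1) = a
        xdot, pdot = oc.estimation_dynamics(
            lin1d, np.array([1.0]), np.array([1.0]), y=np.array([2.0])
        )
        assert xdot[0] == pytest.approx(-1.3 - 1.0)
        assert pdot[0] == pytest.approx(1.3)

    def test_compiled_field_matches_reference(self, l96_5d):
        """The sympy-compiled estimation-dynamics field agrees with the
        direct numpy implementation."""
        rng = np.random.default_rng(7)
        field = build_ocdspe_field(l96_5d, [0, 3])
        for _ in range(5):
            x, p = rng.normal(0, 3, size=(2, 5))
            yv = rng.normal(0, 3, size=2)
            y = np.zeros(5)
            y[[0, 3]] = yv
            z = np.concatenate([x, p])[:, None]
            out = field.f(z, np.array([8.0]), data=yv[:, None])
            xdot, pdot = oc.estimation_dynamics(l96_5d, x, p, y=y)
            assert np.allclose(out[:5, 0], xdot)
            assert np.allclose(out[5:, 0], pdot)


class TestPenalizedObjective:
    def test_zero_residual_equals_cost(self, lin1d, lin_twin):
        traj, obs = lin_twin
        prob = oc.EstimationProblem(lin1d, obs, method="lsq")
        v = np.concatenate([traj.states.ravel(), [1.3]])
        f0 = prob.penalized_objective(v, 0)
        # exact solution: residuals at discretization error, cost = 0
        assert f0 == pytest.approx(oc.cost_lsq(traj.states, obs), abs=1e-8)

    def test_nondecreasing_in_beta(self, lin1d, lin_twin):
        _, obs = lin_twin
        prob = oc.EstimationProblem(lin1d, obs, method="lsq", seed=0)
        v = prob.sample_init(np.random.default_rng(0))
        vals = [prob.penalized_objective(v, b) for b in range(6)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("method", ["lsq", "dspe", "ocdspe"])
    @pytest.mark.parametrize("which", ["l96", "ml"])
    def test_gradient_matches_finite_differences(self, l96_5d, ml, method, which):
        """Exact gradients for every objective (rtol 1e-5) on small random
        instances of both model families."""
        rng = np.random.default_rng(11)
        if which == "l96":
            model = l96_5d
            grid = oc.TimeGrid(0.0, 0.016, 11)
            traj = oc.integrate(model, oc.transient_state(model, seed=1), grid)
            obs = oc.observe(traj, oc.ObservationOperator(5, (0, 3)), 1.0, seed=2)
        else:
            model = ml
            grid = oc.TimeGrid(0.0, 0.05, 9)
            stim = oc.Stimulus(grid, rng.uniform(0, 100, 9))
            traj = oc.integrate(model, np.array([-60.0, 0.1]), grid, stimulus=stim)
            obs = oc.observe(traj, oc.ObservationOperator(2, (0,)), 2.0, seed=3, stimulus=stim)
        prob = oc.EstimationProblem(model, obs, method=method, seed=4)
        # a tame interior point: truth-ish states, small momenta/controls,
        # parameters jittered around the registry values
        parts = [
            (traj.states + rng.normal(0, 0.3, traj.states.shape)).clip(
                prob.bounds.state_box(model)[:, :1] + 1e-3,
                prob.bounds.state_box(model)[:, 1:] - 1e-3,
            ).ravel()
        ]
        if method == "ocdspe":
            parts.append(rng.uniform(-0.5, 0.5, prob.n_aux))
        elif method == "dspe":
            parts.append(rng.uniform(0.1, 3.0, prob.n_aux))
        th = model.param_set.values_array[prob.fit_idx] * rng.uniform(0.9, 1.1, prob.n_par)
        th[th == 0] = 0.05
        parts.append(th)
        v = np.concatenate(parts)
        lam = 11.7
        _, g = prob.objective(v, lam)
        for j in rng.choice(prob.n_free, size=min(50, prob.n_free), replace=False):
            eps = 1e-6 * max(1.0, abs(v[j]))
            e = np.zeros(prob.n_free)
            e[j] = eps
            fd = (prob.objective(v + e, lam)[0] - prob.objective(v - e, lam)[0]) / (2 * eps)
            assert g[j] == pytest.approx(fd, rel=1e-5, abs=1e-6)


class TestAnnealing:
    @pytest.mark.parametrize("method", ["lsq", "dspe", "ocdspe"])
    def test_linear_model_recovery_vs_oracle(self, lin1d, lin_twin, method):
        """All three estimators recover the decay rate of a fully observed
        noiseless linear model to within 1e-3 of a grid-search oracle."""
        from scipy.optimize import minimize_scalar

        traj, obs = lin_twin
        t = obs.grid.t
        y = obs.y[0]
        # independent oracle: 1D least squares over the decay rate with the
        # initial condition read off the data
        oracle = minimize_scalar(
            lambda a: np.sum((y[0] * np.exp(-a * t) - y) ** 2), bounds=(0.1, 5.0),
            method="bounded",
        ).x
        ms = oc.EstimationProblem(lin1d, obs, method=method, q=2, seed=5, max_iter=500).fit()
        assert ms.best.theta_hat["a"] == pytest.approx(oracle, abs=1e-3)
        assert ms.best.theta_hat["a"] == pytest.approx(1.3, abs=1e-3)

    def test_annealing_enforces_constraints(self, lin1d, lin_twin):
        _, obs = lin_twin
        prob = oc.EstimationProblem(lin1d, obs, method="ocdspe", q=1, seed=6, max_iter=500)
        r = prob.fit().best
        first = r.trace[0]["resid_norm"]
        last = r.trace[-1]["resid_norm"]
        assert last <= 1e-3 * max(first, 1e-12) or last < 1e-9

    def test_objective_decreases_within_each_beta(self, lin1d, lin_twin):
        _, obs = lin_twin
        prob = oc.EstimationProblem(lin1d, obs, method="dspe", q=1, seed=7, max_iter=300)
        rng = np.random.default_rng(0)
        v = prob.sample_init(rng)
        r = prob.anneal(v)
        # final objective at each beta never exceeds the warm-start value
        vstart = v
        for tr in r.trace:
            f_start = prob.objective(vstart, tr["lam"])[0]
            assert tr["cost"] + tr["penalty"] <= f_start + 1e-9
            break  # only the first beta has a recorded external start

    def test_perfect_initialization_is_retained(self, lin1d, lin_twin):
        """From the exact states, zero momenta and true parameter on
        noiseless data, annealing keeps the estimate at the truth."""
        traj, obs = lin_twin
        prob = oc.EstimationProblem(lin1d, obs, method="ocdspe", q=1, seed=8, max_iter=300)
        v0 = np.concatenate([traj.states.ravel(), np.zeros(prob.n_aux), [1.3]])
        r = prob.anneal(v0)
        assert r.theta_hat["a"] == pytest.approx(1.3, abs=1e-4)
        assert r.E < 1e-6

    def test_dspe_with_frozen_controls_matches_lsq_objective(self, l96_5d, l96_5d_twin):
        _, obs = l96_5d_twin
        lsq = oc.EstimationProblem(l96_5d, obs, method="lsq", seed=9)
        dspe = oc.EstimationProblem(l96_5d, obs, method="dspe", seed=9)
        rng = np.random.default_rng(2)
        v_lsq = lsq.sample_init(rng)
        x = v_lsq[: lsq.n_x]
        th = v_lsq[lsq.n_x :]
        v_dspe = np.concatenate([x, np.zeros(dspe.n_aux), th])
        for lam in (1.0, 64.0):
            assert dspe.objective(v_dspe, lam)[0] == pytest.approx(
                lsq.objective(v_lsq, lam)[0], rel=1e-12
            )


class TestMultistart:
    def test_single_run(self, lin1d, lin_twin):
        _, obs = lin_twin
        ms = oc.EstimationProblem(lin1d, obs, method="lsq", q=1, seed=1, max_iter=100).fit()
        assert len(ms.runs) == 1 and ms.best_index == 0

    def test_seed_determinism(self, lin1d, lin_twin):
        _, obs = lin_twin
        kw = dict(method="dspe", q=2, seed=123, max_iter=100)
        a = oc.EstimationProblem(lin1d, obs, **kw).fit()
        b = oc.EstimationProblem(lin1d, obs, **kw).fit()
        assert a.best_index == b.best_index
        for ra, rb in zip(a.runs, b.runs):
            assert ra.E == rb.E
            assert ra.theta_hat == rb.theta_hat

    def test_best_has_lowest_E(self, lin1d, lin_twin):
        _, obs = lin_twin
        ms = oc.EstimationProblem(lin1d, obs, method="lsq", q=3, seed=2, max_iter=100).fit()
        assert all(ms.best.E <= r.E for r in ms.runs)

    def test_summary_mentions_parameters(self, lin1d, lin_twin):
        _, obs = lin_twin
        ms = oc.EstimationProblem(lin1d, obs, method="ocdspe", q=1, seed=3, max_iter=50).fit()
        s = ms.summary()
        assert "a" in s and "measurement error" in ms.best.summary()


class TestPredict:
    def test_true_continuation(self, l96_5d):
        grid = oc.TimeGrid(0.0, 0.016, 51)
        x0 = oc.transient_state(l96_5d, seed=12)
        full = oc.integrate(l96_5d, x0, oc.TimeGrid(0.0, 0.016, 101))
        head = oc.integrate(l96_5d, x0, grid)
        cont = oc.predict(
            l96_5d, {"F": 8.0}, head.states[:, -1], oc.TimeGrid(grid.t_end, 0.016, 51)
        )
        assert np.allclose(cont.states, full.states[:, 50:], atol=1e-5)

    def test_degenerate_window(self, l96_5d):
        x = np.arange(5.0)
        out = oc.predict(l96_5d, {"F": 8.0}, x, oc.TimeGrid(0.0, 0.016, 1))
        assert out.states.shape == (5, 1)
        assert np.array_equal(out.states[:, 0], x)
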