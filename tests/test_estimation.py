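"""Input discretization, simulation, objectives, refinement and the solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fispo.estimation import (
    Experiment,
    PiecewiseInput,
    SolveBudget,
    TrackingProblem,
    estimate_uncertainty,
    experiments_to_frame,
    frame_to_experiments,
    objective,
    parameterize_input,
    refine_elements,
    simulate,
    solve,
)
from fispo.model_core import load_fixture


class TestPiecewiseInput:
    def test_single_element_midpoint_is_average(self):
        pw = parameterize_input(1, 0.0, 10.0)
        assert pw.node_times.tolist() == [0.0, 10.0]
        assert pw(np.array([2.0, 8.0]), 5.0) == pytest.approx(5.0)

    def test_four_elements_have_five_equidistant_nodes(self):
        pw = parameterize_input(4, 0.0, 8.0)
        assert np.allclose(pw.node_times, [0, 2, 4, 6, 8])

    @given(c=st.floats(-5, 5), t=st.floats(0, 10))
    @settings(max_examples=25, deadline=None)
    def test_constant_nodes_give_constant_input(self, c, t):
        pw = parameterize_input(3, 0.0, 10.0)
        assert pw(np.full(4, c), t) == pytest.approx(c)

    def test_piecewise_constant_basis(self):
        pw = parameterize_input(2, 0.0, 10.0, kind="constant")
        vals = np.array([1.0, 3.0])
        assert pw(vals, 2.0) == 1.0 and pw(vals, 7.0) == 3.0

    def test_invalid_element_count_rejected(self):
        with pytest.raises(ValueError):
            parameterize_input(0, 0.0, 1.0)

    @given(vals=st.lists(st.floats(-2, 2), min_size=3, max_size=3))
    @settings(max_examples=25, deadline=None)
    def test_refinement_nests_exactly(self, vals):
        coarse = parameterize_input(2, 0.0, 6.0)
        fine = coarse.refine()
        fine_vals = coarse.interpolate_to(fine, vals)
        for t in np.linspace(0, 6, 13):
            assert fine(fine_vals, t) == pytest.approx(coarse(np.array(vals), t))


class TestSimulate:
    def test_c2m_zero_input_zero_state_stays_at_rest(self, c2m_k1e_known):
        t = np.linspace(0, 5, 11)
        xs, ys = simulate(
            c2m_k1e_known, {"k12": 0.8, "k21": 0.6}, [0.0, 0.0],
            w={"w": 0.0}, t_grid=t,
        )
        assert np.allclose(xs, 0.0, atol=1e-12)
        assert np.allclose(ys, 0.0, atol=1e-12)

    def test_hiv_without_infection_decays_in_closed_form(self, hiv):
        """With eta = 0 the infected compartment is linear: TI(0) e^{-dt}."""
        theta = {"lam": 1.0, "rho": 0.1, "delta": 0.5, "N": 10.0, "c": 3.0}
        t = np.linspace(0, 10, 21)
        xs, _ = simulate(hiv, theta, [10.0, 0.5, 2.0], w={"eta": 0.0}, t_grid=t)
        assert np.allclose(xs[:, 1], 0.5 * np.exp(-0.5 * t), rtol=1e-6)

    def test_toggle_switch_steady_state_consistency(self, toggle_switch_reformulated):
        """Root-found fixed point under constant inputs has ~zero dynamics."""
        from scipy.optimize import fsolve

        theta = {"k01": 0.2, "k1": 2.5, "n_TetR": 2.0,
                 "k02": 0.3, "k2": 2.0, "n_LacI": 3.0}
        w1, w2 = 0.3, 1.2

        def f(x):
            x1, x2 = x
            return [
                theta["k01"] + theta["k1"] / (1 + (x2 / (1 + w1)) ** theta["n_TetR"]) - x1,
                theta["k02"] + theta["k2"] / (1 + (x1 / (1 + w2)) ** theta["n_LacI"]) - x2,
            ]

        xstar = fsolve(f, [1.0, 1.0], xtol=1e-13)
        assert np.max(np.abs(f(xstar))) < 1e-10
        # simulating from the fixed point stays there
        t = np.linspace(0, 5, 6)
        xs, _ = simulate(
            toggle_switch_reformulated, theta, xstar,
            w={"w1": w1, "w2": w2}, t_grid=t,
        )
        assert np.allclose(xs, xstar, atol=1e-6)


def _tiny_problem(noisy=False):
    model = load_fixture("c2m_k1e_known")
    t = np.linspace(0, 6, 8)
    theta = {"k12": 0.8, "k21": 0.6}
    _, y = simulate(model, theta, [1.0, 0.5], w={"w": lambda s: 0.5 + 0.1 * s},
                    t_grid=t)
    sigma = np.full_like(y, 0.05 if noisy else 1.0)
    exp = Experiment(id="e1", t=t, y=y, sigma=sigma)
    pw = {"w": parameterize_input(1, 0.0, 6.0)}
    return TrackingProblem(
        model=model,
        experiments=[exp],
        input_param=pw,
        theta_bounds={"k12": (0.1, 3.0), "k21": (0.1, 3.0)},
        x0_bounds={"x2": (0.0, 3.0)},
        w_bounds={"w": (0.0, 3.0)},
        objective="nll" if noisy else "wls",
    ), np.array([0.8, 0.6, 0.5, 0.5, 1.1])  # true decision vector


class TestObjective:
    def test_zero_residual_wls_cost_is_zero(self):
        prob, xt = _tiny_problem()
        assert objective(prob, xt) == pytest.approx(0.0, abs=1e-12)

    def test_zero_residual_nll_is_gaussian_normalizer(self):
        prob, xt = _tiny_problem(noisy=True)
        expected = sum(
            math.log(math.sqrt(2 * math.pi) * s)
            for e in prob.experiments
            for s in e.sigma.ravel()
        )
        assert objective(prob, xt) == pytest.approx(expected, rel=1e-6)

    def test_single_unit_sigma_point(self):
        """One sample, sigma = 1, residual r: -log L = r^2/2 + log(2 pi)/2."""
        model = load_fixture("c2m_k1e_known")
        t = np.array([0.0])
        exp = Experiment(id="e", t=t, y=np.array([[2.0]]), sigma=np.array([[1.0]]))
        prob = TrackingProblem(
            model=model,
            experiments=[exp],
            input_param={"w": parameterize_input(1, 0.0, 1.0)},
            theta_bounds={"k12": (0.1, 3.0), "k21": (0.1, 3.0)},
            x0_bounds={"x2": (0.0, 3.0)},
            w_bounds={"w": (0.0, 3.0)},
            objective="nll",
        )
        # y(0) = x1(0) = 1.0 -> residual r = 1 - 2 = -1
        x = np.array([0.8, 0.6, 0.5, 1.0, 1.0])
        assert objective(prob, x) == pytest.approx(0.5 + 0.5 * math.log(2 * math.pi))

    def test_nonpositive_sigma_rejected_for_likelihood(self):
        model = load_fixture("c2m_k1e_known")
        exp = Experiment(
            id="e", t=np.array([0.0]), y=np.array([[1.0]]), sigma=np.array([[0.0]])
        )
        with pytest.raises(ValueError, match="sigma"):
            TrackingProblem(
                model=model,
                experiments=[exp],
                input_param={"w": parameterize_input(1, 0.0, 1.0)},
                theta_bounds={"k12": (0.1, 3.0), "k21": (0.1, 3.0)},
                x0_bounds={"x2": (0.0, 3.0)},
                w_bounds={"w": (0.0, 3.0)},
                objective="nll",
            )

    def test_inverted_bounds_rejected(self):
        model = load_fixture("c2m_k1e_known")
        exp = Experiment(
            id="e", t=np.array([0.0]), y=np.array([[1.0]]), sigma=np.array([[1.0]])
        )
        with pytest.raises(ValueError, match="bound"):
            TrackingProblem(
                model=model,
                experiments=[exp],
                input_param={"w": parameterize_input(1, 0.0, 1.0)},
                theta_bounds={"k12": (3.0, 0.1), "k21": (0.1, 3.0)},
                x0_bounds={"x2": (0.0, 3.0)},
                w_bounds={"w": (0.0, 3.0)},
            )


class TestRefinement:
    def test_warm_start_cost_equals_coarse_cost(self):
        prob, xt = _tiny_problem()
        result = solve(prob, SolveBudget(de_popsize=4, de_maxiter=5,
                                         polish_maxiter=60), seed=0)
        refined, warm = refine_elements(prob, result)
        assert refined.input_param["w"].n_e == 2
        assert objective(refined, warm) == pytest.approx(result.cost, abs=1e-9)

    def test_warm_start_reproduces_coarse_input_at_old_nodes(self):
        prob, xt = _tiny_problem()
        result = solve(prob, SolveBudget(de_popsize=4, de_maxiter=5,
                                         polish_maxiter=60), seed=0)
        refined, warm = refine_elements(prob, result)
        _, _, wnodes = refined.unpack(warm)
        coarse = result.w_nodes["e1"]["w"]
        pw_c = prob.input_param["w"]
        pw_f = refined.input_param["w"]
        for t in pw_c.node_times:
            assert pw_f(wnodes["e1"]["w"], t) == pytest.approx(pw_c(coarse, t))


class TestSolve:
    def test_seeded_determinism_and_optimality_sanity(self):
        prob, xt = _tiny_problem()
        budget = SolveBudget(de_popsize=4, de_maxiter=10, polish_maxiter=100)
        r1 = solve(prob, budget, seed=7)
        r2 = solve(prob, budget, seed=7)
        assert np.allclose(r1.x, r2.x)
        assert r1.cost == pytest.approx(r2.cost)
        # the returned optimum is (to solver tolerance) at least as good
        # as the true point
        assert r1.cost <= objective(prob, xt) + 1e-6
        # self-consistency: stored cost is reproducible from the estimates
        assert objective(prob, r1.x) == pytest.approx(r1.cost, rel=1e-12, abs=1e-12)
        # all estimates within their declared bounds
        for v, (lo, hi) in zip(r1.x, prob.decision_bounds()):
            assert lo - 1e-12 <= v <= hi + 1e-12

    def test_uncertainty_returns_positive_stds(self):
        prob, xt = _tiny_problem(noisy=True)
        budget = SolveBudget(de_popsize=4, de_maxiter=10, polish_maxiter=100)
        res = solve(prob, budget, seed=3)
        std = estimate_uncertainty(prob, res)
        assert set(std) == set(prob.decision_names())
        assert all(v >= 0 for v in std.values())


class TestGradientConsistency:
    def test_objective_agrees_with_central_differences(self):
        """Directional slope from well-separated points matches interior FD."""
        prob, xt = _tiny_problem()
        direction = np.array([1.0, -0.5, 0.3, 0.2, -0.1])
        direction /= np.linalg.norm(direction)
        h = 1e-4
        f = lambda a: objective(prob, xt + a * direction)
        slope_fd = (f(h) - f(-h)) / (2 * h)
        slope_fd2 = (f(2 * h) - f(-2 * h)) / (4 * h)
        # Richardson-consistent: both estimates agree to leading order
        assert slope_fd == pytest.approx(slope_fd2, abs=1e-4 + 0.05 * abs(slope_fd))


class TestDataTables:
    def test_frame_round_trip(self):
        prob, _ = _tiny_problem(noisy=True)
        df = experiments_to_frame(prob.experiments)
        assert set(df.columns) == {
            "experiment_id", "time", "output_id", "value", "sigma"
        }
        back = frame_to_experiments(df)
        assert len(back) == 1
        np.testing.assert_allclose(back[0].y, prob.experiments[0].y)
        np.testing.assert_allclose(back[0].sigma, prob.experiments[0].sigma)
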