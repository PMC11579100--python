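"""Penalized solves, continuation, augmented Lagrangian and oracles on the
analytically solvable toy problems."""

import numpy as np
import pytest

from optidose import (
    ALConfig,
    PenaltyConfig,
    augmented_lagrangian,
    continuation,
    feasibility_report,
    finite_difference_gradient,
    grid_oracle,
    solve_penalized,
)
from optidose.fixtures import make_toy_problem


@pytest.fixture(scope="module")
def toy_point():
    return make_toy_problem("point_constraint_1cpt")


class TestFiniteDifferenceGradient:
    def test_exact_on_quadratic(self):
        A = np.diag([2.0, 5.0])
        b = np.array([1.0, -3.0])
        f = lambda x: 0.5 * x @ A @ x + b @ x
        x = np.array([0.7, -1.2])
        np.testing.assert_allclose(
            finite_difference_gradient(f, x, 1e-5), A @ x + b, rtol=1e-7
        )

    def test_zero_for_constant_objective(self):
        g = finite_difference_gradient(lambda x: 4.2, np.array([1.0, 2.0, 3.0]), 1e-5)
        np.testing.assert_array_equal(g, 0.0)

    def test_matches_complex_step_oracle_on_penalized_toy_objective(self, toy_point):
        """Independent differentiation route: complex-step derivative of the
        closed-form penalized objective of the toy problem."""
        model = toy_point.problem.model
        ke, V = model.theta["ke"], model.theta["V"]
        tf, c, rho = 10.0, 5.0, 100.0
        a = (1 - np.exp(-ke * tf)) / (V * ke)
        b = np.exp(-ke * tf) / V

        def f(D):
            # smooth on the violating branch D < c/b
            return a * D[0] + 0.5 * rho * (c - b * D[0]) ** 2

        D = np.array([8.0])  # violating: c - bD > 0
        h = 1e-30
        cs = (a * (D[0] + 1j * h) + 0.5 * rho * (c - b * (D[0] + 1j * h)) ** 2).imag / h
        fd = finite_difference_gradient(f, D, 1e-6)[0]
        assert fd == pytest.approx(cs, rel=1e-6)

    def test_one_sided_fallback_at_the_boundary(self):
        f = lambda x: float(x[0] ** 2)
        g = finite_difference_gradient(
            f, np.array([0.0]), 1e-5, bounds=(np.array([0.0]), np.array([1.0]))
        )
        assert g[0] == pytest.approx(0.0, abs=1e-4)


class TestSolvePenalized:
    def test_toy_optimum_matches_analytic_penalized_minimizer(self, toy_point):
        """At finite rho the quadratic-penalty minimizer sits at
        D* - a/(rho b^2), slightly inside the infeasible side."""
        model = toy_point.problem.model
        ke, V = model.theta["ke"], model.theta["V"]
        tf = 10.0
        a = (1 - np.exp(-ke * tf)) / (V * ke)
        b = np.exp(-ke * tf) / V
        rho = 1e4
        expected = toy_point.D_star[0] - a / (rho * b * b)
        res = solve_penalized(toy_point.problem, PenaltyConfig(rho=rho), toy_point.D_init)
        assert res.D_star[0] == pytest.approx(expected, abs=1e-3)
        assert res.converged

    def test_projected_gradient_is_small_at_reported_optimum(self, toy_point):
        res = solve_penalized(toy_point.problem, PenaltyConfig(rho=100.0), toy_point.D_init)
        assert res.gradient_norm <= 1e-4 * (1.0 + abs(res.OFV))

    def test_infeasible_start_warns(self, toy_point):
        with pytest.warns(UserWarning, match="infeasible"):
            solve_penalized(toy_point.problem, PenaltyConfig(rho=10.0), [6.0])

    def test_out_of_bounds_start_rejected(self, toy_point):
        with pytest.raises(ValueError, match="bounds"):
            solve_penalized(toy_point.problem, PenaltyConfig(rho=10.0), [500.0])


class TestContinuation:
    def test_iterates_approach_the_constrained_optimum_from_below(self, toy_point):
        results = continuation(toy_point.problem, [10.0, 100.0, 1e3, 1e4], toy_point.D_init)
        D = np.array([r.D_star[0] for r in results])
        assert np.all(np.diff(D) > 0)  # monotone approach
        assert np.all(D < toy_point.D_star[0] + 1e-9)
        assert D[-1] == pytest.approx(toy_point.D_star[0], abs=0.01)

    def test_inactive_constraint_gives_identical_stages(self):
        toy = make_toy_problem("unconstrained_1cpt")
        results = continuation(toy.problem, [10.0, 100.0], toy.D_init)
        assert results[0].D_star == pytest.approx(results[1].D_star)
        assert all(not r.breakdown.PFV for r in results)

    def test_non_increasing_schedule_rejected(self, toy_point):
        with pytest.raises(ValueError, match="increasing"):
            continuation(toy_point.problem, [100.0, 10.0], toy_point.D_init)


class TestAugmentedLagrangian:
    def test_disabled_updates_reproduce_continuation_bitwise(self, toy_point):
        sched = (10.0, 100.0)
        cont = continuation(toy_point.problem, sched, toy_point.D_init)
        al = augmented_lagrangian(
            toy_point.problem,
            ALConfig(rho_schedule=sched, update_multipliers=False),
            toy_point.D_init,
        )
        for a, b in zip(cont, al):
            assert np.array_equal(a.D_star, b.D_star)
            assert a.OFV == b.OFV

    def test_multiplier_converges_to_kkt_multiplier(self, toy_point):
        results = augmented_lagrangian(
            toy_point.problem,
            ALConfig(rho_schedule=(10.0, 100.0), n_outer=4),
            toy_point.D_init,
        )
        lam = results[-1].lambdas["trough"]
        assert lam == pytest.approx(toy_point.multiplier, rel=1e-3)
        # and the iterate reaches the exact constrained optimum
        assert results[-1].D_star[0] == pytest.approx(toy_point.D_star[0], abs=1e-3)

    def test_inactive_constraint_keeps_multiplier_at_zero(self):
        toy = make_toy_problem("point_constraint_1cpt")
        # lower the threshold and raise the dose floor so the bound-constrained
        # optimum leaves the trough constraint strictly slack
        from dataclasses import replace

        slack = replace(toy.problem.constraints[0], threshold=0.05)
        toy.problem.constraints = (slack,)
        toy.problem.scenario.D_min = np.array([2.0])
        results = augmented_lagrangian(
            toy.problem, ALConfig(rho_schedule=(10.0,), n_outer=3), toy.D_init
        )
        assert results[-1].lambdas["trough"] == 0.0
        assert results[-1].D_star[0] == pytest.approx(2.0)


class TestGridOracle:
    def test_matches_analytic_optimum_on_convex_problem(self):
        toy = make_toy_problem("unconstrained_1cpt")
        res = grid_oracle(toy.problem, PenaltyConfig(rho=10.0), toy.grid)
        assert res["D_star"][0] == pytest.approx(toy.D_star[0], abs=1e-3)

    def test_agrees_with_solver_on_all_one_dimensional_toys(self):
        for kind in ("point_constraint_1cpt", "path_constraint_1cpt", "interval_1cpt"):
            toy = make_toy_problem(kind)
            cfg = PenaltyConfig(rho=1e4)
            res = solve_penalized(toy.problem, cfg, toy.D_init)
            oracle = grid_oracle(toy.problem, cfg, toy.grid)
            assert abs(res.D_star[0] - oracle["D_star"][0]) <= 0.1, kind

    def test_more_than_two_dimensions_unsupported(self):
        problem = make_toy_problem("point_constraint_1cpt").problem
        problem.scenario.m = 3
        with pytest.raises(ValueError, match="at most 2"):
            grid_oracle(problem, PenaltyConfig(rho=1.0), np.arange(3))


class TestMultiStart:
    def test_feasible_starts_agree_on_the_interval_toy(self):
        toy = make_toy_problem("interval_1cpt")
        finals = [
            solve_penalized(toy.problem, PenaltyConfig(rho=1e4), [s]).D_star[0]
            for s in (7.0, 9.0, 11.0)
        ]
        assert max(finals) - min(finals) <= 0.1


class TestFeasibilityReport:
    def test_feasible_verdict_names_margin(self, toy_point):
        # large rho: the residual violation of the penalized optimum is tiny
        res = solve_penalized(toy_point.problem, PenaltyConfig(rho=1e6), toy_point.D_init)
        report = feasibility_report(res)
        assert "feasible within tolerance" in report
        assert "margin" in report

    def test_infeasible_verdict_names_largest_violator(self, toy_point):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = solve_penalized(
                toy_point.problem, PenaltyConfig(rho=10.0), [6.0], maxiter=0
            )
        report = feasibility_report(res, tolerance=1e-6)
        assert "infeasible" in report and "trough" in report

    def test_unconstrained_problem_reports_no_constraints(self):
        toy = make_toy_problem("unconstrained_1cpt")
        res = solve_penalized(toy.problem, PenaltyConfig(rho=1.0), toy.D_init)
        assert "no state constraints" in feasibility_report(res)
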