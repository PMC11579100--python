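"""Penalty functions evaluated against closed-form synthetic observables."""

import numpy as np
import pytest

from optidose import (
    Constraint,
    ConstraintKind,
    CostFunctional,
    Direction,
    PenaltyConfig,
    build_example_problem,
    cost_value,
    duration_penalty,
    mean_value,
    phr_penalty,
    point_penalty,
    quadratic_path_penalty,
)
from optidose.objectives import assemble_objective, phr_point_penalty
from optidose.fixtures import (
    DEFAULT_SEED,
    make_synthetic_observable,
    random_synthetic_trajectory,
)


def path_constraint(threshold, direction=Direction.lower_bound, window=(0.0, 20.0)):
    return Constraint(
        name="c", kind=ConstraintKind.path, observable="x",
        direction=direction, threshold=threshold, window=window,
    )


class TestCost:
    def test_zero_observable_gives_zero_cost(self):
        traj = make_synthetic_observable("constant", value=0.0, window=(12, 32))
        assert cost_value(traj, CostFunctional("x", (12, 32))) == 0.0

    def test_unit_observable_integrates_to_window_length(self):
        traj = make_synthetic_observable("constant", value=1.0, window=(12, 32))
        assert cost_value(traj, CostFunctional("x", (12, 32))) == pytest.approx(20.0)


class TestQuadraticPathPenalty:
    def test_feasible_trajectory_has_zero_penalty(self):
        traj = make_synthetic_observable("constant", value=2.0)
        assert quadratic_path_penalty(traj, path_constraint(1.0), rho=1e6) == 0.0

    def test_constant_violation_half_rho_gsq_times_length(self):
        # g = 1 - x = 0.5 on a window of length 20, rho = 10 -> 25
        traj = make_synthetic_observable("constant", value=0.5)
        assert quadratic_path_penalty(traj, path_constraint(1.0), 10.0) == pytest.approx(25.0)

    def test_penalty_is_linear_in_rho(self, rng):
        traj = random_synthetic_trajectory(rng)
        c = path_constraint(0.3)
        p1 = quadratic_path_penalty(traj, c, 7.0)
        p10 = quadratic_path_penalty(traj, c, 70.0)
        assert p10 == pytest.approx(10.0 * p1, rel=1e-12)

    def test_pfv_over_rho_is_rho_free(self, rng):
        traj = random_synthetic_trajectory(rng)
        c = path_constraint(0.3)
        ratios = [quadratic_path_penalty(traj, c, rho) / rho for rho in (1.0, 10.0, 1e4)]
        np.testing.assert_allclose(ratios, ratios[0], rtol=1e-10)


class TestPHRPenalty:
    def test_zero_multiplier_recovers_quadratic_penalty_exactly(self):
        traj = make_synthetic_observable("constant", value=0.5)
        c = path_constraint(1.0)
        assert phr_penalty(traj, c, 0.0, 10.0) == pytest.approx(25.0, rel=1e-12)

    def test_slack_constraint_with_positive_multiplier_is_negative(self):
        # lambda = 2, rho = 4, g = -10 on window length 1 -> (0 - 4)/8 = -0.5
        traj = make_synthetic_observable("constant", value=11.0, window=(0, 1))
        c = path_constraint(1.0, window=(0, 1))  # g = 1 - 11 = -10
        assert phr_penalty(traj, c, 2.0, 4.0) == pytest.approx(-0.5)

    def test_active_boundary_with_multiplier_is_zero(self):
        # g = 0: max{0, lambda}^2 - lambda^2 = 0
        traj = make_synthetic_observable("constant", value=1.0, window=(0, 1))
        c = path_constraint(1.0, window=(0, 1))
        assert phr_penalty(traj, c, 2.0, 4.0) == pytest.approx(0.0, abs=1e-15)

    def test_matches_quadratic_penalty_on_100_random_trajectories(self):
        rng = np.random.default_rng(DEFAULT_SEED)
        c = path_constraint(0.2)
        for _ in range(100):
            traj = random_synthetic_trajectory(rng)
            rho = float(rng.uniform(0.5, 1e4))
            q = quadratic_path_penalty(traj, c, rho)
            p = phr_penalty(traj, c, 0.0, rho)
            assert p == pytest.approx(q, rel=1e-10, abs=1e-300)

    def test_negative_multiplier_rejected(self, rng):
        traj = random_synthetic_trajectory(rng)
        with pytest.raises(ValueError, match="nonnegative"):
            phr_penalty(traj, path_constraint(0.0), -1.0, 10.0)


class TestScalarPenalties:
    def point_constraint(self, threshold, direction, t=32.0):
        return Constraint(
            name="p", kind=ConstraintKind.point, observable="x",
            direction=direction, threshold=threshold, window=(t, t),
        )

    def test_satisfied_point_constraint(self):
        traj = make_synthetic_observable("constant", value=3.5, window=(0, 32))
        c = self.point_constraint(3.0, Direction.lower_bound)
        assert point_penalty(traj, c, 1e4) == 0.0

    def test_violated_point_constraint(self):
        traj = make_synthetic_observable("constant", value=2.0, window=(0, 32))
        c = self.point_constraint(3.0, Direction.lower_bound)
        assert point_penalty(traj, c, 1e4) == pytest.approx(5000.0)

    def test_violated_mean_value_constraint(self):
        traj = make_synthetic_observable("constant", value=110.0, window=(6, 24))
        c = Constraint(
            name="m", kind=ConstraintKind.mean_value, observable="x",
            direction=Direction.upper_bound, threshold=100.0, window=(6.0, 24.0),
        )
        assert point_penalty(traj, c, 100.0) == pytest.approx(5000.0)

    @pytest.mark.parametrize("tau, rho, expected", [(5.0, 1e4, 0.0), (7.0, 1e4, 2e4), (0.0, 1e4, 0.0)])
    def test_duration_penalty_on_excess_time(self, tau, rho, expected):
        traj = make_synthetic_observable("constant", value=1.0, window=(0, 32))
        traj.augmented["tau::d"] = tau
        c = Constraint(
            name="d", kind=ConstraintKind.duration, observable="x",
            threshold=0.0, window=(0.0, 32.0), sub_threshold=1.5, max_duration=5.0,
        )
        assert duration_penalty(traj, c, rho) == pytest.approx(expected)

    def test_scalar_phr_reduces_to_quadratic_at_zero_multiplier(self):
        traj = make_synthetic_observable("constant", value=2.0, window=(0, 32))
        c = self.point_constraint(3.0, Direction.lower_bound)
        assert phr_point_penalty(traj, c, 0.0, 1e4) == pytest.approx(
            point_penalty(traj, c, 1e4), rel=1e-12
        )


class TestMeanValue:
    def test_constant_and_zero(self):
        traj = make_synthetic_observable("constant", value=100.0, window=(6, 24))
        assert mean_value(traj, "x", (6.0, 24.0)) == pytest.approx(100.0)
        traj = make_synthetic_observable("constant", value=0.0, window=(6, 24))
        assert mean_value(traj, "x", (6.0, 24.0)) == 0.0

    def test_linear_ramp_has_midpoint_mean(self):
        traj = make_synthetic_observable("linear", window=(6, 24))
        assert mean_value(traj, "x", (6.0, 24.0)) == pytest.approx(15.0)

    def test_zero_length_window_rejected(self):
        traj = make_synthetic_observable("constant", value=1.0)
        with pytest.raises(ValueError, match="positive length"):
            mean_value(traj, "x", (6.0, 6.0))


class TestAssembledObjective:
    def test_zero_doses_are_feasible_with_untreated_tumor_cost(self, fast_sim):
        """No drug: neutrophils stay at baseline (PFV = 0) and the cost equals
        the untreated tumor burden integral."""
        problem = build_example_problem("tumor")
        f = assemble_objective(problem, PenaltyConfig(rho=1e4), sim_opts=fast_sim)
        bd = f(np.zeros(4))
        assert bd.PFV["neutropenia"] == 0.0
        # independent route: simulate untreated and integrate W by trapezoid
        from optidose.models import untreated_baseline

        traj = untreated_baseline(problem.model, np.linspace(0, 32, 201))
        t, W = traj.t_grid, traj.observables["W"]
        mask = t >= 12.0
        expected = np.trapezoid(W[mask], t[mask])
        assert bd.CFV == pytest.approx(expected, rel=1e-4)

    def test_recommended_initial_dose_is_feasible(self, fast_sim):
        problem = build_example_problem("tumor")
        f = assemble_objective(problem, PenaltyConfig(rho=1e4), sim_opts=fast_sim)
        bd = f(np.full(4, 10.0))
        assert bd.PFV["neutropenia"] == 0.0

    def test_ofv_is_cfv_plus_pfvs_to_machine_precision(self, fast_sim):
        problem = build_example_problem("tumor")
        f = assemble_objective(problem, PenaltyConfig(rho=10.0), sim_opts=fast_sim)
        bd = f(np.full(4, 60.0))  # infeasible: nonzero penalty
        assert bd.PFV["neutropenia"] > 0
        assert bd.OFV - bd.CFV - sum(bd.PFV.values()) == 0.0
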