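"""Synthetic trajectories and analytically solvable toy dosing problems.

Everything the test suite asserts about penalties, quadrature and the
optimizer is anchored to objects from this module whose correct values are
known in closed form: constant/linear/crossing observables for the penalty
integrals, random band-limited observables for penalty identities, and
one-compartment toy problems whose constrained optimum (and Lagrange
multiplier) follow from elementary calculus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dosing import DoseRecord, DosingScenario, OptimizationMode
from .models import build_example_model
from .objectives import Constraint, ConstraintKind, CostFunctional, Direction
from .optimize import OCProblem

__all__ = [
    "DEFAULT_SEED",
    "SyntheticTrajectory",
    "make_synthetic_observable",
    "random_synthetic_trajectory",
    "ToyProblem",
    "make_toy_problem",
]

DEFAULT_SEED = 20241008


@dataclass
class SyntheticTrajectory:
    """A closed-form observable sampled on a grid, duck-typed to the parts of
    the simulated-trajectory contract the penalty evaluators use."""

    t_grid: np.ndarray
    observables: dict[str, np.ndarray]
    augmented: dict[str, float]

    def observable_at(self, name: str, t: float) -> float:
        return float(np.interp(t, self.t_grid, self.observables[name]))


def make_synthetic_observable(
    spec: str,
    window: tuple[float, float] = (0.0, 20.0),
    n_points: int = 401,
    value: float = 0.5,
    threshold: float = 1.5,
    crossings: tuple[float, float] = (10.0, 20.0),
    name: str = "x",
) -> SyntheticTrajectory:
    """Build a synthetic observable with exactly known functional values.

    ``constant`` — the observable equals ``value`` everywhere;
    ``linear`` — it equals t;
    ``crossing`` — it sits one unit above ``threshold``, dips linearly to one
    unit below between the two ``crossings`` (hitting the threshold exactly
    at those times), giving a below-threshold duration of
    ``crossings[1] - crossings[0]``.
    """
    a, b = window
    down, up = crossings
    knots = sorted({a, b, down, up, 0.5 * (down + up)})
    t = np.unique(np.concatenate([np.linspace(a, b, n_points), np.asarray(knots)]))
    if spec == "constant":
        v = np.full_like(t, float(value))
    elif spec == "linear":
        v = t.copy()
    elif spec == "crossing":
        mid = 0.5 * (down + up)
        xp = [a, down, mid, up, b]
        fp = [threshold + 1, threshold, threshold - 1, threshold, threshold + 1]
        v = np.interp(t, xp, fp)
    else:
        raise ValueError(f"unknown synthetic spec {spec!r}")
    return SyntheticTrajectory(t_grid=t, observables={name: v}, augmented={})


def random_synthetic_trajectory(
    rng: np.random.Generator,
    window: tuple[float, float] = (0.0, 20.0),
    n_points: int = 301,
    name: str = "x",
    scale: float = 2.0,
) -> SyntheticTrajectory:
    """A random band-limited observable taking both signs of violation
    around typical thresholds — input for penalty-identity property tests."""
    a, b = window
    t = np.linspace(a, b, n_points)
    k = np.arange(1, 6)
    coeff = rng.normal(size=(2, k.size)) * scale / k
    phase = 2 * np.pi * (t[:, None] - a) / (b - a) * k[None, :]
    v = rng.normal() + np.sin(phase) @ coeff[0] + np.cos(phase) @ coeff[1]
    return SyntheticTrajectory(t_grid=t, observables={name: v}, augmented={})


@dataclass
class ToyProblem:
    """A toy optimal-dosing problem bundled with its analytic solution."""

    problem: OCProblem
    D_init: np.ndarray
    D_star: np.ndarray
    multiplier: float | None
    grid: np.ndarray
    description: str

    def penalized_optimum(self, rho: float) -> np.ndarray:
        """Analytic minimizer of the quadratic-penalty problem at finite rho
        (only defined for the point-constraint toy)."""
        raise NotImplementedError


def make_toy_problem(kind: str) -> ToyProblem:
    """Toy problems on the linear one-compartment model (V=1, ke=0.1).

    ``point_constraint_1cpt``: minimize drug AUC over [0, 10] subject to
    C(10) >= 5 with a single bolus at t=0.  Since C(t) = D e^{-ke t}, the
    constraint is active at the optimum: D* = c e^{ke tf}, and the KKT
    multiplier is mu = (1 - e^{-ke tf}) e^{ke tf} / ke.

    ``path_constraint_1cpt``: same but C(t) >= 5 on [5, 10]; C decreases, so
    the path constraint binds at tf and the optimum coincides.

    ``unconstrained_1cpt``: no constraint; the AUC is increasing in D, so
    the optimum sits at the lower dose bound.

    ``interval_1cpt``: two fixed boluses of 20 at t=0 and t=theta on [0, 24]
    with the safety cap C(24) <= 8 on the trough.  The AUC over [0, tf]
    decreases as the second dose moves later while the trough rises with
    theta, so the optimum activates the cap:
    theta* = tf + ln(c/D - e^{-ke tf}) / ke.
    """
    model = build_example_model("toy_1cpt")
    ke, V = model.theta["ke"], model.theta["V"]

    if kind in ("point_constraint_1cpt", "path_constraint_1cpt", "unconstrained_1cpt"):
        tf, c = 10.0, 5.0
        scenario = DosingScenario(
            records=(DoseRecord(time=0.0, group=1),),
            t0=0.0,
            tf=tf,
            m=1,
            D_min=[0.0],
            D_max=[200.0],
            time_unit="hour",
        )
        cost = CostFunctional(observable="C", window=(0.0, tf))
        if kind == "unconstrained_1cpt":
            scenario.D_min = np.array([2.0])
            problem = OCProblem(model, scenario, cost, (), name=kind)
            return ToyProblem(
                problem=problem,
                D_init=np.array([10.0]),
                D_star=np.array([2.0]),
                multiplier=None,
                grid=np.arange(2.0, 50.0, 1.0),
                description="cost monotone in dose: optimum at the lower bound",
            )
        if kind == "point_constraint_1cpt":
            constraint = Constraint(
                name="trough",
                kind=ConstraintKind.point,
                observable="C",
                direction=Direction.lower_bound,
                threshold=c,
                window=(tf, tf),
            )
        else:
            constraint = Constraint(
                name="floor",
                kind=ConstraintKind.path,
                observable="C",
                direction=Direction.lower_bound,
                threshold=c,
                window=(5.0, tf),
            )
        problem = OCProblem(model, scenario, cost, (constraint,), name=kind)
        D_star = c * V * np.exp(ke * tf)
        mu = (1.0 - np.exp(-ke * tf)) * np.exp(ke * tf) / ke
        return ToyProblem(
            problem=problem,
            D_init=np.array([30.0]),  # feasible: C(10) = 30 e^{-1} > 5
            D_star=np.array([D_star]),
            multiplier=float(mu),
            grid=np.arange(5.0, 60.0, 1.0),
            description="active trough constraint: D* = c V e^{ke tf}",
        )

    if kind == "interval_1cpt":
        tf, dose, c = 24.0, 20.0, 8.0
        scenario = DosingScenario(
            records=(
                DoseRecord(time=0.0, amount=dose, group=1),
                DoseRecord(time=0.0, amount=dose, group=2),
            ),
            t0=0.0,
            tf=tf,
            m=1,
            D_min=[6.0],
            D_max=[23.0],
            mode=OptimizationMode.optimize_intervals,
            time_unit="hour",
        )
        cost = CostFunctional(observable="C", window=(0.0, tf))
        constraint = Constraint(
            name="trough_cap",
            kind=ConstraintKind.point,
            observable="C",
            direction=Direction.upper_bound,
            threshold=c,
            window=(tf, tf),
        )
        problem = OCProblem(model, scenario, cost, (constraint,), name=kind)
        theta_star = tf + np.log(c * V / dose - np.exp(-ke * tf)) / ke
        return ToyProblem(
            problem=problem,
            D_init=np.array([9.0]),  # feasible: trough below the cap
            D_star=np.array([theta_star]),
            multiplier=None,
            grid=np.arange(6.0, 23.0 + 1e-9, 0.25),
            description="trough-cap-active dosing interval: "
            "theta* = tf + ln(c V / D - e^{-ke tf}) / ke",
        )

    raise ValueError(f"unknown toy problem kind {kind!r}")
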