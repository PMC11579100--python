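"""Cost functionals, state constraints and penalty transformations.

A state constraint is normalized internally to ``g(y(t, D)) <= 0``: lower
bounds on an observable become ``g = threshold - obs``, upper bounds
``g = obs - threshold``.  Four constraint kinds are supported:

* ``path`` — the inequality holds pointwise on a time window,
* ``point`` — it holds at a single time point,
* ``mean_value`` — it holds for the window average of the observable,
* ``duration`` — the time the observable spends beyond ``sub_threshold``
  must not exceed ``max_duration``.

Path violations are penalized by the quadratic (Moreau–Yosida) penalty
``rho/2 * ∫ max{0, g}² dt`` or, with a multiplier function λ(t) >= 0, by the
Powell–Hestenes–Rockafellar augmented-Lagrangian penalty
``1/(2 rho) * ∫ max{0, λ + rho g}² - λ² dt`` (which reduces to the quadratic
penalty for λ = 0).  Scalar constraints use the pointwise analogue
``rho/2 * max{0, g}²``.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np

from .simulate import (
    DurationSpec,
    QuadratureSpec,
    Trajectory,
    integral_functional,
    simulate,
)

__all__ = [
    "CostFunctional",
    "Constraint",
    "ConstraintKind",
    "Direction",
    "PenaltyConfig",
    "ObjectiveBreakdown",
    "cost_value",
    "quadratic_path_penalty",
    "point_penalty",
    "duration_penalty",
    "phr_penalty",
    "phr_point_penalty",
    "scalar_violation",
    "mean_value",
    "constraint_margin",
    "assemble_objective",
]


class ConstraintKind(str, Enum):
    path = "path"
    point = "point"
    duration = "duration"
    mean_value = "mean_value"


class Direction(str, Enum):
    lower_bound = "lower_bound"
    upper_bound = "upper_bound"


@dataclass(frozen=True)
class CostFunctional:
    """Secondary-target cost: integral of an observable over a window, or its
    value at a time point (window with t1 = t2)."""

    observable: str
    window: tuple[float, float]
    type: str = "integral"  # "integral" | "point"


@dataclass(frozen=True)
class Constraint:
    name: str
    kind: ConstraintKind
    observable: str
    direction: Direction = Direction.lower_bound
    threshold: float = 0.0
    window: tuple[float, float] = (0.0, 0.0)
    max_duration: float | None = None
    sub_threshold: float | None = None
    smoothing_eps: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "kind", ConstraintKind(self.kind))
        object.__setattr__(self, "direction", Direction(self.direction))
        if self.window[1] < self.window[0]:
            raise ValueError(f"constraint {self.name!r}: reversed window")
        if self.kind is ConstraintKind.duration:
            if self.max_duration is None or self.sub_threshold is None:
                raise ValueError(
                    f"constraint {self.name!r}: duration kind needs "
                    "max_duration and sub_threshold"
                )

    def g(self, value):
        """Signed violation: constraint satisfied iff g <= 0."""
        value = np.asarray(value, dtype=float)
        if self.direction is Direction.lower_bound:
            return self.threshold - value
        return value - self.threshold


@dataclass
class PenaltyConfig:
    """Penalty parameters: a scalar applied to every constraint, or a
    per-constraint mapping.  ``schedule`` drives continuation runs."""

    rho: float | Mapping[str, float] = 1e4
    schedule: Sequence[float | Mapping[str, float]] | None = None

    def rho_for(self, name: str) -> float:
        if isinstance(self.rho, Mapping):
            try:
                r = float(self.rho[name])
            except KeyError:
                raise KeyError(f"no penalty parameter for constraint {name!r}") from None
        else:
            r = float(self.rho)
        if r <= 0:
            raise ValueError(f"penalty parameter for {name!r} must be > 0")
        return r

    def with_rho(self, rho) -> "PenaltyConfig":
        return PenaltyConfig(rho=rho, schedule=self.schedule)


@dataclass
class ObjectiveBreakdown:
    """CFV, per-constraint PFVs, and their sum OFV for one dose vector."""

    D: np.ndarray
    CFV: float
    PFV: dict[str, float]
    PFV_over_rho: dict[str, float]
    margins: dict[str, float]
    trajectory: Trajectory | None = None

    @property
    def OFV(self) -> float:
        return self.CFV + sum(self.PFV.values())


# ---------------------------------------------------------------------------
# evaluation on trajectories (simulated or synthetic)

def _window_series(traj, observable: str, window: tuple[float, float]):
    t = np.asarray(traj.t_grid, dtype=float)
    v = np.asarray(traj.observables[observable], dtype=float)
    mask = (t >= window[0] - 1e-9) & (t <= window[1] + 1e-9)
    if mask.sum() < 2:
        raise ValueError(f"window {window} covers fewer than two grid points")
    return t[mask], v[mask]


def _value_at(traj, observable: str, time: float) -> float:
    if hasattr(traj, "observable_at"):
        try:
            return float(traj.observable_at(observable, time))
        except (IndexError, ValueError):
            pass
    t = np.asarray(traj.t_grid, dtype=float)
    v = np.asarray(traj.observables[observable], dtype=float)
    return float(np.interp(time, t, v))


def cost_value(traj, cost: CostFunctional) -> float:
    """CFV: the cost quadrature state at tf (or the point value)."""
    if cost.type == "point":
        return _value_at(traj, cost.observable, cost.window[0])
    aug = getattr(traj, "augmented", {})
    if "cost" in aug:
        return float(aug["cost"])
    t, v = _window_series(traj, cost.observable, cost.window)
    return float(np.trapezoid(v, t))


def quadratic_path_penalty(traj, c: Constraint, rho: float) -> float:
    """``rho/2 * ∫ max{0, g}² dt`` over the constraint window.

    Uses the trajectory's augmented violation integral when the simulation
    carried one; otherwise quadrature on the dense grid.
    """
    if c.kind is not ConstraintKind.path:
        raise ValueError(f"constraint {c.name!r} is not a path constraint")
    aug = getattr(traj, "augmented", {})
    key = f"viol::{c.name}"
    if key in aug:
        return 0.5 * rho * float(aug[key])
    t, v = _window_series(traj, c.observable, c.window)
    viol = np.maximum(0.0, c.g(v))
    return 0.5 * rho * float(np.trapezoid(viol**2, t))


def _as_lambda_fn(lam) -> Callable[[np.ndarray], np.ndarray]:
    if lam is None:
        return lambda t: np.zeros_like(np.asarray(t, dtype=float))
    if callable(lam):
        return lam
    if np.isscalar(lam):
        lv = float(lam)
        if lv < 0:
            raise ValueError("multiplier must be nonnegative")
        return lambda t: np.full_like(np.asarray(t, dtype=float), lv)
    nodes, values = np.asarray(lam[0], dtype=float), np.asarray(lam[1], dtype=float)
    if np.any(values < 0):
        raise ValueError("multiplier must be nonnegative pointwise")
    return lambda t: np.interp(t, nodes, values)


def phr_penalty(traj, c: Constraint, lam, rho: float) -> float:
    """Powell–Hestenes–Rockafellar penalty
    ``1/(2 rho) * ∫ max{0, λ(t) + rho g}² - λ(t)² dt``.

    λ may be a scalar, a ``(nodes, values)`` pair (interpolated piecewise
    linearly) or a callable.  With λ ≡ 0 this equals the quadratic penalty;
    it can be negative where λ > 0 and the constraint is slack.
    """
    if c.kind is not ConstraintKind.path:
        raise ValueError(f"constraint {c.name!r} is not a path constraint")
    aug = getattr(traj, "augmented", {})
    key = f"phr::{c.name}"
    if key in aug:
        return float(aug[key])
    lam_fn = _as_lambda_fn(lam)
    t, v = _window_series(traj, c.observable, c.window)
    lam_t = np.asarray(lam_fn(t), dtype=float)
    if np.any(lam_t < 0):
        raise ValueError("multiplier must be nonnegative pointwise")
    integrand = (np.maximum(0.0, lam_t + rho * c.g(v)) ** 2 - lam_t**2) / (2.0 * rho)
    return float(np.trapezoid(integrand, t))


def mean_value(traj, observable: str, window: tuple[float, float]) -> float:
    """Window average of an observable (e.g. mean bacterial count)."""
    length = window[1] - window[0]
    if length <= 0:
        raise ValueError("mean_value needs a window of positive length")
    aug = getattr(traj, "augmented", {})
    key = f"int::{observable}_{window[0]:g}_{window[1]:g}"
    if key in aug:
        return float(aug[key]) / length
    t, v = _window_series(traj, observable, window)
    return float(np.trapezoid(v, t)) / length


def _scalar_violation(traj, c: Constraint) -> float:
    if c.kind is ConstraintKind.point:
        return float(c.g(_value_at(traj, c.observable, c.window[0])))
    if c.kind is ConstraintKind.mean_value:
        return float(c.g(mean_value(traj, c.observable, c.window)))
    if c.kind is ConstraintKind.duration:
        aug = getattr(traj, "augmented", {})
        key = f"tau::{c.name}"
        if key not in aug:
            raise KeyError(
                f"trajectory carries no duration state for constraint {c.name!r}"
            )
        return float(aug[key]) - float(c.max_duration)
    raise ValueError(f"constraint {c.name!r} has no scalar violation")


def scalar_violation(traj, c: Constraint) -> float:
    """Signed violation g for point-type constraints (satisfied iff g <= 0)."""
    return _scalar_violation(traj, c)


def point_penalty(traj, c: Constraint, rho: float) -> float:
    """``rho/2 * max{0, g}²`` for point, mean-value and duration constraints."""
    viol = _scalar_violation(traj, c)
    return 0.5 * rho * max(0.0, viol) ** 2


def phr_point_penalty(traj, c: Constraint, lam: float, rho: float) -> float:
    """Scalar Powell–Hestenes–Rockafellar penalty
    ``(max{0, λ + rho g}² - λ²) / (2 rho)`` for point-type constraints."""
    lam = float(lam)
    if lam < 0:
        raise ValueError("multiplier must be nonnegative")
    viol = _scalar_violation(traj, c)
    return (max(0.0, lam + rho * viol) ** 2 - lam**2) / (2.0 * rho)


def duration_penalty(traj, c: Constraint, rho: float) -> float:
    """Penalty on excess time beyond the allowed duration (``tau - max_duration``)."""
    if c.kind is not ConstraintKind.duration:
        raise ValueError(f"constraint {c.name!r} is not a duration constraint")
    return point_penalty(traj, c, rho)


def constraint_margin(traj, c: Constraint) -> float:
    """The reportable margin quantity: worst observable value on the window
    (path), the point value, the window mean, or the accumulated duration."""
    if c.kind is ConstraintKind.path:
        t, v = _window_series(traj, c.observable, c.window)
        return float(v.min() if c.direction is Direction.lower_bound else v.max())
    if c.kind is ConstraintKind.point:
        return _value_at(traj, c.observable, c.window[0])
    if c.kind is ConstraintKind.mean_value:
        return mean_value(traj, c.observable, c.window)
    aug = getattr(traj, "augmented", {})
    return float(aug[f"tau::{c.name}"])


# ---------------------------------------------------------------------------
# assembling the penalized objective

def build_functionals(problem, penalty_config: PenaltyConfig, lambdas=None):
    """Quadrature/duration specs needed to evaluate CFV and every PFV
    in a single simulation."""
    specs: list[QuadratureSpec | DurationSpec] = []
    cost = problem.cost
    if cost.type == "integral":
        specs.append(integral_functional(cost.observable, cost.window, name="cost"))
    lambdas = lambdas or {}
    for c in problem.constraints:
        if c.kind is ConstraintKind.path:
            lam = lambdas.get(c.name)
            if lam is not None and not _lambda_is_zero(lam):
                rho = penalty_config.rho_for(c.name)
                lam_fn = _as_lambda_fn(lam)
                specs.append(
                    QuadratureSpec(
                        name=f"phr::{c.name}",
                        observable=c.observable,
                        window=c.window,
                        integrand=lambda v, t, g=c.g, lam_fn=lam_fn, rho=rho: (
                            np.maximum(0.0, lam_fn(t) + rho * g(v)) ** 2
                            - np.asarray(lam_fn(t)) ** 2
                        )
                        / (2.0 * rho),
                    )
                )
            else:
                specs.append(
                    QuadratureSpec(
                        name=f"viol::{c.name}",
                        observable=c.observable,
                        window=c.window,
                        integrand=lambda v, t, g=c.g: np.maximum(0.0, g(v)) ** 2,
                    )
                )
        elif c.kind is ConstraintKind.mean_value:
            specs.append(
                integral_functional(
                    c.observable,
                    c.window,
                    name=f"int::{c.observable}_{c.window[0]:g}_{c.window[1]:g}",
                )
            )
        elif c.kind is ConstraintKind.duration:
            specs.append(
                DurationSpec(
                    name=f"tau::{c.name}",
                    observable=c.observable,
                    threshold=float(c.sub_threshold),
                    smoothing_eps=c.smoothing_eps,
                    below=c.direction is Direction.lower_bound,
                )
            )
    return specs


def _lambda_is_zero(lam) -> bool:
    if lam is None:
        return True
    if np.isscalar(lam):
        return float(lam) == 0.0
    if callable(lam):
        return False
    return not np.any(np.asarray(lam[1], dtype=float) != 0.0)


def evaluate_breakdown(
    problem,
    traj: Trajectory,
    penalty_config: PenaltyConfig,
    lambdas=None,
    D=None,
    keep_trajectory: bool = False,
) -> ObjectiveBreakdown:
    """Read CFV, PFVs and margins off a trajectory simulated with the specs
    from :func:`build_functionals`."""
    lambdas = lambdas or {}
    cfv = cost_value(traj, problem.cost)
    pfv: dict[str, float] = {}
    pfv_over_rho: dict[str, float] = {}
    margins: dict[str, float] = {}
    for c in problem.constraints:
        rho = penalty_config.rho_for(c.name)
        if c.kind is ConstraintKind.path:
            lam = lambdas.get(c.name)
            if lam is not None and not _lambda_is_zero(lam):
                p = phr_penalty(traj, c, lam, rho)
            else:
                p = quadratic_path_penalty(traj, c, rho)
        else:
            lam = lambdas.get(c.name)
            if lam is not None and not _lambda_is_zero(lam):
                p = phr_point_penalty(traj, c, float(lam), rho)
            else:
                p = point_penalty(traj, c, rho)
        pfv[c.name] = p
        pfv_over_rho[c.name] = p / rho
        margins[c.name] = constraint_margin(traj, c)
    return ObjectiveBreakdown(
        D=np.asarray(D, dtype=float) if D is not None else np.asarray([]),
        CFV=cfv,
        PFV=pfv,
        PFV_over_rho=pfv_over_rho,
        margins=margins,
        trajectory=traj if keep_trajectory else None,
    )


def assemble_objective(
    problem,
    penalty_config: PenaltyConfig,
    lambdas=None,
    sim_opts: dict | None = None,
    keep_trajectory: bool = False,
) -> Callable[[np.ndarray], ObjectiveBreakdown]:
    """Return a callable ``D -> ObjectiveBreakdown``.

    One simulation per evaluation computes the cost and every penalty
    functional through augmented quadrature states; OFV = CFV + Σ PFV holds
    by construction.
    """
    from .dosing import OptimizationMode, expand_doses, expand_intervals

    sim_opts = dict(sim_opts or {})
    specs = build_functionals(problem, penalty_config, lambdas)
    scenario = problem.scenario
    # point constraints and point costs need their times on the breakpoint grid
    extra_times = [
        c.window[0]
        for c in problem.constraints
        if c.kind is ConstraintKind.point
    ]
    if problem.cost.type == "point":
        extra_times.append(problem.cost.window[0])
    if extra_times:
        from dataclasses import replace

        scenario = replace(
            scenario,
            support_times=tuple(sorted(set(scenario.support_times) | set(extra_times))),
        )

    def objective(D) -> ObjectiveBreakdown:
        D = np.atleast_1d(np.asarray(D, dtype=float))
        if scenario.mode is OptimizationMode.optimize_doses:
            events = expand_doses(D, scenario)
        else:
            events = expand_intervals(D, scenario)
        traj = simulate(problem.model, events, scenario, functionals=specs, **sim_opts)
        return evaluate_breakdown(
            problem, traj, penalty_config, lambdas, D=D, keep_trajectory=keep_trajectory
        )

    return objective
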