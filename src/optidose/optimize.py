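"""Box-constrained solution of the penalized optimal-dosing problem.

The state-constrained problem (minimize a cost functional subject to state
constraints and dose bounds) is transformed into a sequence of unconstrained
problems: minimize CFV + Σ PFV over the dose box.  Each stage is solved by a
projected quasi-Newton method (L-BFGS-B) with central finite-difference
gradients; an outer loop either increases the penalty parameter
(continuation) or additionally updates the multiplier function
(safeguarded augmented Lagrangian).  With multiplier updates disabled the
augmented-Lagrangian loop reproduces plain continuation exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .dosing import DosingScenario, DoseVector
from .models import PKPDModel
from .objectives import (
    Constraint,
    ConstraintKind,
    CostFunctional,
    ObjectiveBreakdown,
    PenaltyConfig,
    assemble_objective,
)

__all__ = [
    "OCProblem",
    "SolveResult",
    "ALConfig",
    "solve_penalized",
    "continuation",
    "augmented_lagrangian",
    "finite_difference_gradient",
    "grid_oracle",
    "feasibility_report",
]

DEFAULT_FEASIBILITY_TOL = 1e-2


@dataclass
class OCProblem:
    """A complete optimal-dosing problem: model + scenario + cost + constraints."""

    model: PKPDModel
    scenario: DosingScenario
    cost: CostFunctional
    constraints: tuple[Constraint, ...] = ()
    name: str = "problem"

    def __post_init__(self):
        self.constraints = tuple(self.constraints)
        for c in self.constraints:
            if c.observable not in self.model.observables:
                raise ValueError(
                    f"constraint {c.name!r} references unknown observable "
                    f"{c.observable!r}"
                )
        if self.cost.observable not in self.model.observables:
            raise ValueError(f"cost references unknown observable {self.cost.observable!r}")


@dataclass
class SolveResult:
    D_star: np.ndarray
    breakdown: ObjectiveBreakdown
    gradient_norm: float
    n_evaluations: int
    converged: bool
    feasible: bool
    min_constraint_margin: dict[str, float]
    rho: float | Mapping[str, float]
    trace: list[dict] = field(default_factory=list)
    lambdas: dict | None = None
    message: str = ""

    @property
    def OFV(self) -> float:
        return self.breakdown.OFV


@dataclass
class ALConfig:
    """Safeguarded augmented-Lagrangian settings.

    The standard Powell–Hestenes–Rockafellar update
    ``λ⁺(t) = max{0, λ(t) + rho * g(y(t, D*))}`` is applied pointwise on a
    node grid over each path-constraint window, capped at ``lambda_max``.
    """

    rho_schedule: Sequence[float | Mapping[str, float]] = (1e2,)
    n_outer: int = 5
    n_lambda_nodes: int = 101
    lambda_max: float = 1e6
    update_multipliers: bool = True


def finite_difference_gradient(
    objective: Callable[[np.ndarray], float],
    D: np.ndarray,
    relative_step: float = 1e-5,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Central differences with per-coordinate step ``h_i = step * max(|D_i|, 1)``.

    Stencil points outside the box (or raising an error) fall back to a
    one-sided difference on the admissible side.
    """
    D = np.atleast_1d(np.asarray(D, dtype=float))
    grad = np.empty_like(D)
    lo = -np.inf * np.ones_like(D) if bounds is None else np.asarray(bounds[0], float)
    hi = np.inf * np.ones_like(D) if bounds is None else np.asarray(bounds[1], float)
    f0 = None
    for i in range(D.size):
        h = relative_step * max(abs(D[i]), 1.0)
        up, dn = D.copy(), D.copy()
        up[i] += h
        dn[i] -= h
        use_up = up[i] <= hi[i]
        use_dn = dn[i] >= lo[i]
        try:
            fu = objective(up) if use_up else None
        except (RuntimeError, FloatingPointError):
            fu, use_up = None, False
        try:
            fd = objective(dn) if use_dn else None
        except (RuntimeError, FloatingPointError):
            fd, use_dn = None, False
        if use_up and use_dn:
            grad[i] = (fu - fd) / (2 * h)
        elif use_up or use_dn:
            if f0 is None:
                f0 = objective(D)
            grad[i] = (fu - f0) / h if use_up else (f0 - fd) / h
        else:
            raise RuntimeError(f"no admissible finite-difference stencil at index {i}")
    return grad


def _projected_gradient_norm(grad, D, lo, hi, tol=1e-12):
    pg = grad.copy()
    at_lo = D <= lo + tol
    at_hi = D >= hi - tol
    pg[at_lo] = np.minimum(pg[at_lo], 0.0)
    pg[at_hi] = np.maximum(pg[at_hi], 0.0)
    return float(np.linalg.norm(pg, ord=np.inf))


def solve_penalized(
    problem: OCProblem,
    penalty_config: PenaltyConfig,
    D_init,
    lambdas=None,
    sim_opts: dict | None = None,
    relative_step: float = 1e-5,
    ftol: float = 1e-10,
    gtol: float = 1e-7,
    maxiter: int = 200,
    feasibility_tol: float = DEFAULT_FEASIBILITY_TOL,
    warn_infeasible: bool = True,
) -> SolveResult:
    """Minimize OFV = CFV + Σ PFV over the dose box from ``D_init``.

    A warning is emitted when the starting point is infeasible (nonzero
    penalty), since large initial violations at large penalty parameters can
    destabilize the ODE solver and the line search.
    """
    if isinstance(D_init, DoseVector):
        D_init = D_init.values
    D_init = np.atleast_1d(np.asarray(D_init, dtype=float))
    lo, hi = problem.scenario.D_min, problem.scenario.D_max
    if np.any(D_init < lo - 1e-12) or np.any(D_init > hi + 1e-12):
        raise ValueError("D_init outside dose bounds")
    evaluate = assemble_objective(problem, penalty_config, lambdas, sim_opts)

    cache: dict[tuple, ObjectiveBreakdown] = {}
    n_eval = 0

    def breakdown_at(D) -> ObjectiveBreakdown:
        nonlocal n_eval
        key = tuple(np.round(np.asarray(D, float), 14))
        if key not in cache:
            cache[key] = evaluate(D)
            n_eval += 1
            if len(cache) > 4096:
                cache.clear()
        return cache[key]

    bd0 = breakdown_at(D_init)
    if warn_infeasible and sum(bd0.PFV.values()) > feasibility_tol:
        warnings.warn(
            f"{problem.name}: initial doses are infeasible "
            f"(sum PFV = {sum(bd0.PFV.values()):.3g}); consider feasible starts",
            stacklevel=2,
        )

    trace: list[dict] = []

    def fun(D) -> float:
        return breakdown_at(D).OFV

    def jac(D) -> np.ndarray:
        g = finite_difference_gradient(fun, D, relative_step, bounds=(lo, hi))
        bd = breakdown_at(D)
        trace.append(
            {
                "D": np.asarray(D, float).copy(),
                "CFV": bd.CFV,
                "PFV": dict(bd.PFV),
                "OFV": bd.OFV,
                "grad_norm": float(np.linalg.norm(g, ord=np.inf)),
            }
        )
        return g

    res = minimize(
        fun,
        D_init,
        jac=jac,
        method="L-BFGS-B",
        bounds=list(zip(lo, hi)),
        options={"ftol": ftol, "gtol": gtol, "maxiter": maxiter},
    )
    D_star = np.clip(res.x, lo, hi)
    bd = breakdown_at(D_star)
    grad = finite_difference_gradient(fun, D_star, relative_step, bounds=(lo, hi))
    pgn = _projected_gradient_norm(grad, D_star, lo, hi)

    # Quasi-Newton line searches can stall against the near-wall curvature of
    # large penalty parameters; polish with a derivative-free pass if the
    # projected gradient is still large relative to the objective scale.
    if pgn > 1e-4 * (1.0 + abs(bd.OFV)):
        polish = minimize(
            fun,
            D_star,
            method="Powell",
            bounds=list(zip(lo, hi)),
            options={"xtol": 1e-8, "ftol": 1e-12, "maxiter": 50 * D_star.size},
        )
        x = np.clip(polish.x, lo, hi)
        if breakdown_at(x).OFV <= bd.OFV:
            D_star = x
            bd = breakdown_at(D_star)
            grad = finite_difference_gradient(fun, D_star, relative_step, bounds=(lo, hi))
            pgn = _projected_gradient_norm(grad, D_star, lo, hi)
            res.success = res.success or polish.success
    feasible = all(p <= feasibility_tol for p in bd.PFV.values())
    return SolveResult(
        D_star=D_star,
        breakdown=bd,
        gradient_norm=pgn,
        n_evaluations=n_eval,
        converged=bool(res.success),
        feasible=feasible,
        min_constraint_margin=dict(bd.margins),
        rho=penalty_config.rho,
        trace=trace,
        lambdas=lambdas,
        message=str(res.message),
    )


def continuation(
    problem: OCProblem,
    rho_schedule: Sequence[float | Mapping[str, float]],
    D_init,
    **solve_opts,
) -> list[SolveResult]:
    """Solve a series of penalized problems with increasing penalty
    parameter, warm-starting each stage from the previous optimum."""
    _check_increasing(rho_schedule)
    results: list[SolveResult] = []
    D = D_init
    for rho in rho_schedule:
        opts = dict(solve_opts)
        if results:
            # warm starts from a penalized optimum are expected to sit
            # marginally on the infeasible side; don't warn about them
            opts.setdefault("warn_infeasible", False)
        try:
            res = solve_penalized(problem, PenaltyConfig(rho=rho), D, **opts)
        except (RuntimeError, ValueError) as exc:
            if results:
                results[-1].message += f" | stage rho={rho} failed: {exc}"
                warnings.warn(f"continuation stage rho={rho} failed: {exc}", stacklevel=2)
                break
            raise
        results.append(res)
        D = res.D_star
    return results


def _check_increasing(schedule):
    def scalarize(rho):
        return float(min(rho.values())) if isinstance(rho, Mapping) else float(rho)

    vals = [scalarize(r) for r in schedule]
    if any(b <= a for a, b in zip(vals, vals[1:])):
        raise ValueError("penalty schedule must be strictly increasing")


def augmented_lagrangian(
    problem: OCProblem,
    al_config: ALConfig,
    D_init,
    sim_opts: dict | None = None,
    **solve_opts,
) -> list[SolveResult]:
    """Safeguarded augmented-Lagrangian outer loop.

    Alternates a penalized solve (PHR penalty) with the pointwise multiplier
    update ``λ⁺ = min(max(0, λ + rho g), lambda_max)`` evaluated on the
    optimal trajectory.  With ``update_multipliers=False`` the multipliers
    stay at zero and the iterates coincide with plain continuation over
    ``rho_schedule``.
    """
    if not al_config.update_multipliers:
        return continuation(
            problem, al_config.rho_schedule, D_init, sim_opts=sim_opts, **solve_opts
        )

    from .objectives import scalar_violation

    path_constraints = [c for c in problem.constraints if c.kind is ConstraintKind.path]
    scalar_constraints = [
        c for c in problem.constraints if c.kind is not ConstraintKind.path
    ]
    lambdas: dict = {
        c.name: (
            np.linspace(c.window[0], c.window[1], al_config.n_lambda_nodes),
            np.zeros(al_config.n_lambda_nodes),
        )
        for c in path_constraints
    }
    lambdas.update({c.name: 0.0 for c in scalar_constraints})

    schedule = list(al_config.rho_schedule)
    results: list[SolveResult] = []
    D = D_init
    for outer in range(al_config.n_outer):
        rho = schedule[min(outer, len(schedule) - 1)]
        cfg = PenaltyConfig(rho=rho)
        opts = dict(solve_opts)
        if outer > 0:
            opts.setdefault("warn_infeasible", False)
        res = solve_penalized(
            problem, cfg, D, lambdas=dict(lambdas), sim_opts=sim_opts, **opts
        )
        # re-simulate at the optimum to evaluate g for the multiplier update
        evaluate = assemble_objective(
            problem, cfg, dict(lambdas), sim_opts, keep_trajectory=True
        )
        bd = evaluate(res.D_star)
        traj = bd.trajectory
        for c in path_constraints:
            nodes, values = lambdas[c.name]
            obs = np.array([traj.observable_at(c.observable, t) for t in nodes])
            new = np.clip(
                np.maximum(0.0, values + cfg.rho_for(c.name) * c.g(obs)),
                0.0,
                al_config.lambda_max,
            )
            lambdas[c.name] = (nodes, new)
        for c in scalar_constraints:
            g = scalar_violation(traj, c)
            lambdas[c.name] = float(
                np.clip(
                    max(0.0, lambdas[c.name] + cfg.rho_for(c.name) * g),
                    0.0,
                    al_config.lambda_max,
                )
            )
        res.lambdas = {
            k: (v[0].copy(), v[1].copy()) if isinstance(v, tuple) else v
            for k, v in lambdas.items()
        }
        results.append(res)
        D = res.D_star
    return results


def grid_oracle(
    problem: OCProblem,
    penalty_config: PenaltyConfig,
    grid_spec,
    sim_opts: dict | None = None,
    refine: bool = True,
) -> dict:
    """Brute-force verification oracle for 1-D and 2-D problems.

    Evaluates the penalized objective on an explicit grid and (for 1-D)
    refines the best bracket with bounded scalar minimization.  Independent
    of the quasi-Newton path by construction.
    """
    m = problem.scenario.m
    if m > 2:
        raise ValueError("grid_oracle supports at most 2 optimized parameters")
    evaluate = assemble_objective(problem, penalty_config, sim_opts=sim_opts)
    axes = _grid_axes(grid_spec, m)
    if m == 1:
        xs = axes[0]
        vals = np.array([evaluate([x]).OFV for x in xs])
        i = int(np.argmin(vals))
        best_x, best_f = float(xs[i]), float(vals[i])
        if refine and 0 < i < len(xs) - 1:
            r = minimize_scalar(
                lambda x: evaluate([x]).OFV,
                bounds=(xs[i - 1], xs[i + 1]),
                method="bounded",
                options={"xatol": 1e-6 * max(1.0, abs(best_x))},
            )
            if r.fun < best_f:
                best_x, best_f = float(r.x), float(r.fun)
        return {"D_star": np.array([best_x]), "OFV": best_f, "grid": xs, "values": vals}
    xs, ys = axes
    vals = np.array([[evaluate([x, y]).OFV for y in ys] for x in xs])
    i, j = np.unravel_index(int(np.argmin(vals)), vals.shape)
    best = np.array([xs[i], ys[j]])
    best_f = float(vals[i, j])
    if refine:
        xlo, xhi = xs[max(i - 1, 0)], xs[min(i + 1, len(xs) - 1)]
        ylo, yhi = ys[max(j - 1, 0)], ys[min(j + 1, len(ys) - 1)]
        fx = np.linspace(xlo, xhi, 9)
        fy = np.linspace(ylo, yhi, 9)
        fvals = np.array([[evaluate([x, y]).OFV for y in fy] for x in fx])
        fi, fj = np.unravel_index(int(np.argmin(fvals)), fvals.shape)
        if fvals[fi, fj] < best_f:
            best = np.array([fx[fi], fy[fj]])
            best_f = float(fvals[fi, fj])
    return {"D_star": best, "OFV": best_f, "grid": axes, "values": vals}


def _grid_axes(grid_spec, m):
    if isinstance(grid_spec, Mapping):
        axis = np.arange(
            grid_spec["start"], grid_spec["stop"] + 0.5 * grid_spec["step"], grid_spec["step"]
        )
        return [axis] * m
    if isinstance(grid_spec, (list, tuple)) and len(grid_spec) == m:
        return [np.asarray(a, dtype=float) for a in grid_spec]
    return [np.asarray(grid_spec, dtype=float)] * m


def feasibility_report(result: SolveResult, tolerance: float = DEFAULT_FEASIBILITY_TOL) -> str:
    """Human-readable per-constraint feasibility summary at the optimum."""
    bd = result.breakdown
    lines = [f"doses: {np.array2string(result.D_star, precision=4)}"]
    lines.append(f"CFV = {bd.CFV:.6g}, OFV = {bd.OFV:.6g}")
    if not bd.PFV:
        lines.append("no state constraints")
        return "\n".join(lines)
    worst_name, worst_p = max(bd.PFV.items(), key=lambda kv: kv[1])
    for name, p in bd.PFV.items():
        lines.append(
            f"constraint {name}: PFV = {p:.4g}, PFV/rho = "
            f"{bd.PFV_over_rho[name]:.4g}, margin = {bd.margins[name]:.6g}"
        )
    if worst_p <= tolerance:
        lines.append(f"verdict: feasible within tolerance {tolerance:g}")
    else:
        lines.append(
            f"verdict: infeasible — largest violation from {worst_name!r} "
            f"(PFV = {worst_p:.4g}); the penalty parameter needs to be further increased"
        )
    return "\n".join(lines)
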