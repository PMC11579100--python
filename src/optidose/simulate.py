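"""Event-aware ODE integration with augmented quadrature states.

Cost and penalty functionals are integrals of (transformed) observables over
time windows.  They are evaluated the same way an AUC is: as additional
state variables integrated alongside the model, started at zero and read off
at the final time.  Integration restarts at every administration, infusion
end, constraint-window endpoint and support time, so boluses enter as exact
state jumps, infusion rates are piecewise constant per segment, and windowed
integrands switch on and off exactly at their endpoints.

The one non-smooth functional — the time an observable spends below a
threshold — is handled outside the ODE: the dense solution is scanned for
threshold crossings, which are refined by root finding, and the
below-threshold measure is summed exactly.  A logistic-smoothed surrogate is
available for optimizers that struggle with the discontinuous indicator.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .dosing import AdminEvent, AdminKind, DosingScenario
from .models import PKPDModel

__all__ = [
    "Trajectory",
    "QuadratureSpec",
    "DurationSpec",
    "integral_functional",
    "duration_state",
    "area_below_threshold",
    "simulate",
    "IntegrationError",
    "ModelError",
]

_EPS = 1e-9


class IntegrationError(RuntimeError):
    """ODE solver failed to meet tolerances; carries the failure time."""

    def __init__(self, message: str, time: float):
        super().__init__(message)
        self.time = time


class ModelError(RuntimeError):
    """Model produced non-finite states."""


@dataclass(frozen=True)
class QuadratureSpec:
    """Augmented state ``q`` with dq/dt = integrand(observable(t), t) inside
    ``window`` and 0 outside; q(t0) = 0, value read at tf."""

    name: str
    observable: str
    window: tuple[float, float]
    integrand: Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass(frozen=True)
class DurationSpec:
    """Time the observable spends below (or above) ``threshold``.

    ``smoothing_eps = 0`` requests exact crossing detection on the dense
    solution; ``smoothing_eps > 0`` integrates the logistic indicator
    ``1/(1 + exp(sign*(obs - threshold)/eps))`` as a quadrature state.
    """

    name: str
    observable: str
    threshold: float
    smoothing_eps: float = 0.0
    below: bool = True
    window: tuple[float, float] | None = None


def integral_functional(
    observable: str,
    window: tuple[float, float],
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
    name: str | None = None,
) -> QuadratureSpec:
    """Quadrature spec for ``∫_window transform(observable) dt``."""
    a, b = float(window[0]), float(window[1])
    if b < a:
        raise ValueError(f"window [{a:g}, {b:g}] is reversed")
    if transform is None:
        integrand = lambda v, t: v
    else:
        integrand = lambda v, t: transform(v)
    return QuadratureSpec(
        name=name or f"int_{observable}_{a:g}_{b:g}",
        observable=observable,
        window=(a, b),
        integrand=integrand,
    )


def duration_state(
    observable: str,
    threshold: float,
    smoothing_eps: float = 0.0,
    below: bool = True,
    name: str | None = None,
) -> DurationSpec:
    """Spec for the total time ``observable < threshold`` (or ``>``)."""
    if smoothing_eps < 0:
        raise ValueError("smoothing_eps must be >= 0")
    return DurationSpec(
        name=name or f"tau_{observable}",
        observable=observable,
        threshold=float(threshold),
        smoothing_eps=float(smoothing_eps),
        below=below,
    )


def area_below_threshold(
    observable: str,
    threshold: float,
    window: tuple[float, float],
    name: str | None = None,
) -> QuadratureSpec:
    """Smooth alternative to a duration constraint: ``∫ max{0, thr - obs} dt``."""
    thr = float(threshold)
    return integral_functional(
        observable,
        window,
        transform=lambda v: np.maximum(0.0, thr - v),
        name=name or f"area_below_{observable}",
    )


@dataclass
class Trajectory:
    """Dense simulation output plus functional values at the final time.

    ``quadrature[name]`` is the running value of each augmented state on
    ``t_grid``; ``augmented[name]`` its value at tf (for exact duration
    states only the final value is defined and the series is absent).
    """

    t_grid: np.ndarray
    states: np.ndarray
    observables: dict[str, np.ndarray]
    quadrature: dict[str, np.ndarray]
    augmented: dict[str, float]
    diagnostics: dict
    model: PKPDModel
    _segments: list = field(default_factory=list, repr=False)

    def state_at(self, t: float) -> np.ndarray:
        t = float(t)
        times = [seg[0] for seg in self._segments]
        i = max(0, bisect.bisect_right(times, t + _EPS) - 1)
        ta, tb, sol = self._segments[i]
        t = min(max(t, ta), tb)
        return np.asarray(sol(t))[: self.model.n]

    def observable_at(self, name: str, t: float) -> float:
        return float(self.model.observe(name, self.state_at(t)))

    def observable_min(self, name: str, window: tuple[float, float] | None = None):
        """Minimum of an observable over a window, refined on the dense output."""
        vals = self.observables[name]
        mask = np.ones_like(self.t_grid, dtype=bool)
        if window is not None:
            mask = (self.t_grid >= window[0] - _EPS) & (self.t_grid <= window[1] + _EPS)
        if not mask.any():
            raise ValueError("window contains no grid points")
        i = int(np.argmin(np.where(mask, vals, np.inf)))
        return float(vals[i]), float(self.t_grid[i])

    def to_frame(self) -> pd.DataFrame:
        data = {"TIME": self.t_grid}
        for k in range(self.states.shape[1]):
            data[f"A{k + 1}"] = self.states[:, k]
        for name, series in self.observables.items():
            data[name] = series
        for name, series in self.quadrature.items():
            data[name] = series
        return pd.DataFrame(data)


def _merge_breakpoints(points: Sequence[float], t0: float, tf: float) -> np.ndarray:
    pts = np.asarray(sorted(set([t0, tf] + [float(p) for p in points])), dtype=float)
    pts = pts[(pts >= t0 - _EPS) & (pts <= tf + _EPS)]
    keep = [pts[0]]
    scale = max(1.0, abs(tf - t0))
    for p in pts[1:]:
        if p - keep[-1] > 1e-12 * scale:
            keep.append(p)
    return np.asarray(keep)


def simulate(
    model: PKPDModel,
    events: Sequence[AdminEvent],
    scenario: DosingScenario,
    functionals: Sequence[QuadratureSpec | DurationSpec] = (),
    rtol: float = 1e-10,
    atol: float = 1e-12,
    method: str = "LSODA",
    dense_points: int = 200,
) -> Trajectory:
    """Integrate ``model`` under ``events`` on ``[scenario.t0, scenario.tf]``.

    Boluses at time s add their amount to the target compartment at s⁺;
    infusions contribute the constant rate amount/duration while active.
    Quadrature functionals are appended as extra states; exact duration
    functionals are evaluated on the dense output afterwards.
    """
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    t0, tf = float(scenario.t0), float(scenario.tf)
    n = model.n
    theta = model.theta

    events = sorted(events, key=lambda e: e.time)
    for e in events:
        if e.time < t0 - _EPS or e.time > tf + _EPS:
            raise ValueError(f"event at t={e.time:g} outside [{t0:g}, {tf:g}]")
        if e.compartment < 1 or e.compartment > n:
            raise ValueError(f"event compartment {e.compartment} outside 1..{n}")

    quad_specs: list[QuadratureSpec] = []
    exact_durations: list[DurationSpec] = []
    for spec in functionals:
        if isinstance(spec, DurationSpec):
            if spec.smoothing_eps > 0:
                thr, eps = spec.threshold, spec.smoothing_eps
                sign = 1.0 if spec.below else -1.0
                quad_specs.append(
                    QuadratureSpec(
                        name=spec.name,
                        observable=spec.observable,
                        window=spec.window or (t0, tf),
                        integrand=lambda v, t, thr=thr, eps=eps, sign=sign: 1.0
                        / (1.0 + np.exp(np.clip(sign * (v - thr) / eps, -500, 500))),
                    )
                )
            else:
                exact_durations.append(spec)
        else:
            a, b = spec.window
            if a < t0 - _EPS or b > tf + _EPS:
                raise ValueError(
                    f"functional {spec.name!r}: window [{a:g}, {b:g}] outside horizon"
                )
            quad_specs.append(spec)

    breakpoints: list[float] = list(scenario.support_times)
    for e in events:
        breakpoints.append(e.time)
        if e.kind is AdminKind.infusion:
            breakpoints.append(min(e.time + e.duration, tf))
    for spec in quad_specs:
        breakpoints.extend(spec.window)
    bps = _merge_breakpoints(breakpoints, t0, tf)

    report = _merge_breakpoints(np.linspace(t0, tf, max(2, dense_points)), t0, tf)
    report = np.unique(np.concatenate([report, bps]))

    obs_fns = {
        spec.observable: model.observables[spec.observable] for spec in quad_specs
    }
    nq = len(quad_specs)

    z = np.concatenate([np.asarray(model.y0(theta), dtype=float), np.zeros(nq)])
    if z.size != n + nq:
        raise ModelError(f"y0 returned length {z.size - nq}, expected {n}")

    t_out: list[float] = []
    z_out: list[np.ndarray] = []
    segments: list[tuple[float, float, object]] = []
    nfev = 0

    for ta, tb in zip(bps[:-1], bps[1:]):
        # apply boluses scheduled at the segment start
        for e in events:
            if e.kind is AdminKind.bolus and abs(e.time - ta) <= _EPS:
                z[e.compartment - 1] += e.amount
        # constant infusion-rate vector on this segment
        u = np.zeros(n)
        tm = 0.5 * (ta + tb)
        for e in events:
            if e.kind is AdminKind.infusion and e.time - _EPS <= tm <= e.time + e.duration + _EPS:
                u[e.compartment - 1] += e.amount / e.duration
        active = [
            spec.window[0] - _EPS <= tm <= spec.window[1] + _EPS for spec in quad_specs
        ]

        def rhs(t, zz, u=u, active=active):
            y = zz[:n]
            dy = model.rhs(t, y, theta, u)
            dq = np.zeros(nq)
            for j, spec in enumerate(quad_specs):
                if active[j]:
                    dq[j] = spec.integrand(obs_fns[spec.observable](y, theta), t)
            return np.concatenate([np.asarray(dy, dtype=float), dq])

        t_eval = report[(report >= ta - _EPS) & (report <= tb + _EPS)]
        sol = solve_ivp(
            rhs,
            (ta, tb),
            z,
            method=method,
            t_eval=t_eval,
            dense_output=True,
            rtol=rtol,
            atol=atol,
        )
        nfev += sol.nfev
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{ta:g}, {tb:g}]: {sol.message}", time=ta
            )
        if not np.all(np.isfinite(sol.y)):
            raise ModelError(f"non-finite state encountered in [{ta:g}, {tb:g}]")
        segments.append((ta, tb, sol.sol))
        # drop the duplicated joint point, keeping the post-dose value at ta
        if t_out and abs(sol.t[0] - t_out[-1]) <= _EPS:
            t_out.pop()
            z_out.pop()
        t_out.extend(sol.t)
        z_out.extend(sol.y.T)
        z = sol.y[:, -1].copy()

    # terminal boluses (administration exactly at tf) are applied but not integrated
    for e in events:
        if e.kind is AdminKind.bolus and abs(e.time - tf) <= _EPS:
            z[e.compartment - 1] += e.amount
            z_out[-1] = z.copy()

    t_grid = np.asarray(t_out)
    Z = np.asarray(z_out)
    states = Z[:, :n]
    quadrature = {spec.name: Z[:, n + j] for j, spec in enumerate(quad_specs)}
    augmented = {name: float(series[-1]) for name, series in quadrature.items()}

    observables = {
        name: np.asarray(fn(states, theta), dtype=float)
        for name, fn in model.observables.items()
    }

    traj = Trajectory(
        t_grid=t_grid,
        states=states,
        observables=observables,
        quadrature=quadrature,
        augmented=augmented,
        diagnostics={"rtol": rtol, "atol": atol, "method": method, "nfev": nfev},
        model=model,
        _segments=segments,
    )

    for spec in exact_durations:
        traj.augmented[spec.name] = _exact_duration(traj, spec)
    return traj


def _exact_duration(traj: Trajectory, spec: DurationSpec) -> float:
    """Measure of {t : observable(t) < threshold} via crossing detection.

    The dense solution of each integration segment is sampled, sign changes
    of observable - threshold are bracketed and refined by Brent's method,
    and the below-threshold measure is accumulated exactly.
    """
    fn = traj.model.observables[spec.observable]
    theta = traj.model.theta
    sign = 1.0 if spec.below else -1.0
    lo, hi = spec.window or (traj.t_grid[0], traj.t_grid[-1])
    total = 0.0
    for ta, tb, sol in traj._segments:
        a, b = max(ta, lo), min(tb, hi)
        if b - a <= _EPS:
            continue

        def f(t):
            return sign * (float(fn(np.asarray(sol(t))[: traj.model.n], theta)) - spec.threshold)

        ts = np.linspace(a, b, 65)
        vals = np.array([f(t) for t in ts])
        crossings = []
        for i in range(len(ts) - 1):
            if vals[i] == 0.0:
                crossings.append(ts[i])
            elif vals[i] * vals[i + 1] < 0:
                crossings.append(brentq(f, ts[i], ts[i + 1], xtol=1e-12))
        nodes = [a] + sorted(crossings) + [b]
        for left, right in zip(nodes[:-1], nodes[1:]):
            if right - left <= 0:
                continue
            if f(0.5 * (left + right)) < 0:
                total += right - left
    return total
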