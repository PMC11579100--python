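"""Dosing scenarios: administration records and their expansion into events.

A dosing *scenario* fixes when and into which compartment drug is given; the
optimizer only moves the dose amounts (``optimize_doses`` mode) or the gap
between administrations (``optimize_intervals`` mode).  Records are grouped:
all records sharing a ``group`` index receive the same optimized amount, so a
regimen of 16 daily administrations with 4 distinct dose levels is optimized
over a 4-vector.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "AdminKind",
    "OptimizationMode",
    "DoseRecord",
    "AdminEvent",
    "DosingScenario",
    "DoseVector",
    "expand_doses",
    "expand_intervals",
    "validate_scenario",
    "ScenarioError",
]


class ScenarioError(ValueError):
    """Raised for ill-formed scenarios or out-of-range dose vectors."""


class AdminKind(str, Enum):
    bolus = "bolus"
    infusion = "infusion"


class OptimizationMode(str, Enum):
    optimize_doses = "optimize_doses"
    optimize_intervals = "optimize_intervals"


@dataclass(frozen=True)
class DoseRecord:
    """One planned administration.

    ``amount`` is the fixed amount used in interval mode; in dose mode the
    amount is supplied by the optimized dose vector through ``group``.
    ``duration`` is required for infusions (zero-order input over that span).
    ``lag`` shifts the effective administration time (absorption lag).
    """

    time: float
    amount: float = 1.0
    compartment: int = 1
    kind: AdminKind = AdminKind.bolus
    duration: float | None = None
    lag: float = 0.0
    group: int = 1
    bioavailability: float = 1.0


@dataclass(frozen=True)
class AdminEvent:
    """A fully resolved administration handed to the simulator."""

    time: float
    amount: float
    compartment: int
    kind: AdminKind
    duration: float = 0.0


@dataclass
class DosingScenario:
    records: tuple[DoseRecord, ...]
    t0: float
    tf: float
    m: int
    D_min: np.ndarray
    D_max: np.ndarray
    support_times: tuple[float, ...] = ()
    mode: OptimizationMode = OptimizationMode.optimize_doses
    time_unit: str = "day"

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        self.D_min = np.atleast_1d(np.asarray(self.D_min, dtype=float))
        self.D_max = np.atleast_1d(np.asarray(self.D_max, dtype=float))
        self.support_times = tuple(float(t) for t in self.support_times)
        self.mode = OptimizationMode(self.mode)


@dataclass(frozen=True)
class DoseVector:
    """Optimized parameters: doses, or the inter-dose gap in interval mode."""

    values: np.ndarray

    def __init__(self, values: Sequence[float]) -> None:
        object.__setattr__(
            self, "values", np.atleast_1d(np.asarray(values, dtype=float))
        )

    def __len__(self) -> int:
        return self.values.size


def _as_values(D: DoseVector | Sequence[float]) -> np.ndarray:
    if isinstance(D, DoseVector):
        return D.values
    return np.atleast_1d(np.asarray(D, dtype=float))


def expand_doses(
    D: DoseVector | Sequence[float], scenario: DosingScenario
) -> list[AdminEvent]:
    """Resolve records into events, drawing amounts from the dose vector.

    Each record ``r`` yields one event of amount
    ``r.bioavailability * D[r.group - 1]`` at time ``r.time + r.lag``; the
    mapping is linear in ``D`` and conserves total administered amount.
    """
    values = _as_values(D)
    if scenario.mode is not OptimizationMode.optimize_doses:
        raise ScenarioError("expand_doses requires mode=optimize_doses")
    if values.size != scenario.m:
        raise ScenarioError(
            f"dose vector has length {values.size}, scenario expects m={scenario.m}"
        )
    events = []
    for i, r in enumerate(scenario.records):
        if not 1 <= r.group <= scenario.m:
            raise ScenarioError(
                f"record {i}: group {r.group} outside 1..{scenario.m}"
            )
        events.append(
            AdminEvent(
                time=r.time + r.lag,
                amount=r.bioavailability * values[r.group - 1],
                compartment=r.compartment,
                kind=r.kind,
                duration=float(r.duration or 0.0),
            )
        )
    return events


def expand_intervals(
    theta: DoseVector | Sequence[float], scenario: DosingScenario
) -> list[AdminEvent]:
    """Resolve records into events with optimized administration times.

    All records sit at time 0 with fixed amounts; the record in group ``g``
    is administered at ``theta[0] * (g - 1)`` (the lag-time construction), so
    a single gap parameter spaces consecutive doses.
    """
    values = _as_values(theta)
    if scenario.mode is not OptimizationMode.optimize_intervals:
        raise ScenarioError("expand_intervals requires mode=optimize_intervals")
    gap = float(values[0])
    events = []
    for i, r in enumerate(scenario.records):
        t = r.time + gap * (r.group - 1) + r.lag
        dur = float(r.duration or 0.0)
        if t + dur > scenario.tf + 1e-12:
            raise ScenarioError(
                f"record {i}: administration at t={t:g} (+{dur:g} infusion) "
                f"exceeds tf={scenario.tf:g}"
            )
        events.append(
            AdminEvent(
                time=t,
                amount=r.bioavailability * r.amount,
                compartment=r.compartment,
                kind=r.kind,
                duration=dur,
            )
        )
    return events


def validate_scenario(scenario: DosingScenario) -> list[str]:
    """Return human-readable invariant violations (empty list = well-formed)."""
    issues: list[str] = []
    if not scenario.t0 < scenario.tf:
        issues.append(f"t0={scenario.t0:g} must be < tf={scenario.tf:g}")
    if scenario.D_min.size != scenario.m or scenario.D_max.size != scenario.m:
        issues.append("D_min/D_max must have length m")
    else:
        bad = np.nonzero(scenario.D_min > scenario.D_max)[0]
        for j in bad:
            issues.append(
                f"D_min[{j}]={scenario.D_min[j]:g} > D_max[{j}]={scenario.D_max[j]:g}"
            )
    used = set()
    for i, r in enumerate(scenario.records):
        used.add(r.group)
        if r.amount < 0:
            issues.append(f"record {i}: negative amount {r.amount:g}")
        if r.lag < 0:
            issues.append(f"record {i}: negative lag {r.lag:g}")
        if r.kind is AdminKind.infusion and not (r.duration and r.duration > 0):
            issues.append(f"record {i}: infusion requires duration > 0")
        if r.kind is AdminKind.bolus and r.duration:
            issues.append(f"record {i}: bolus must not carry a duration")
        if r.compartment < 1:
            issues.append(f"record {i}: compartment must be >= 1")
        if r.group < 1:
            issues.append(f"record {i}: group must be >= 1")
        if scenario.mode is OptimizationMode.optimize_doses:
            # in interval mode the group is the dose number, not an index
            # into the optimized vector
            if r.group > scenario.m:
                issues.append(f"record {i}: group {r.group} outside 1..{scenario.m}")
            t = r.time + r.lag
            if not scenario.t0 <= t <= scenario.tf:
                issues.append(
                    f"record {i}: time+lag {t:g} outside [{scenario.t0:g}, {scenario.tf:g}]"
                )
    if scenario.mode is OptimizationMode.optimize_doses:
        missing = sorted(set(range(1, scenario.m + 1)) - used)
        if missing:
            issues.append(f"unused dose group(s): {missing}")
    else:
        off_zero = [i for i, r in enumerate(scenario.records) if r.time != 0]
        if off_zero:
            issues.append(
                f"interval mode requires all records at time 0 (violated by rows {off_zero})"
            )
    for t in scenario.support_times:
        if not scenario.t0 <= t <= scenario.tf:
            issues.append(f"support time {t:g} outside observation interval")
    return issues
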