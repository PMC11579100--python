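"""PK/PD model abstraction and the bundled example models.

A model is a parameterized ODE system ``dy/dt = f(t, y, theta, u)`` on an
observation interval, with named scalar observables read off the state
(concentration, tumor weight, neutrophil count, ...).  Boluses are applied by
the simulator as instantaneous state jumps; infusions enter through ``u``, a
per-compartment zero-order input-rate vector that is nonzero while an
infusion is running.

The bundled disease models are reconstructions of canonical published model
families — a transit-compartment tumor-kill model coupled to the Friberg
myelosuppression feedback model, an indirect-response (turnover) biomarker
model, and a two-compartment antibiotic PK model with adaptive drug
resistance — with parameter values chosen to give realistic dynamics on the
stated horizons.  They exercise every feature of the optimal-dosing machinery
(multi-group regimens, infusions, path/point/duration/mean-value
constraints); see ``docs/methods.md`` for the full parameter tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "PKPDModel",
    "build_example_model",
    "register_model",
    "untreated_baseline",
    "EXAMPLE_MODELS",
]


@dataclass
class PKPDModel:
    """An ODE-based PK/PD model.

    ``rhs(t, y, theta, u)`` returns dy/dt; ``y0(theta)`` the initial state;
    ``observables`` maps names to functions of ``(y, theta)`` that accept
    states of shape ``(n,)`` or ``(grid, n)``.  ``theta`` is fixed during
    optimization.
    """

    name: str
    n: int
    theta: dict[str, float]
    rhs: Callable[[float, np.ndarray, Mapping[str, float], np.ndarray], np.ndarray]
    y0: Callable[[Mapping[str, float]], np.ndarray]
    observables: dict[str, Callable[[np.ndarray, Mapping[str, float]], np.ndarray]]
    dosing_compartments: frozenset[int] = frozenset({1})
    time_unit: str = "day"
    metadata: dict[str, float] = field(default_factory=dict)

    def with_theta(self, **overrides: float) -> "PKPDModel":
        unknown = set(overrides) - set(self.theta)
        if unknown:
            raise KeyError(f"unknown parameter(s) for {self.name}: {sorted(unknown)}")
        theta = {**self.theta, **overrides}
        return PKPDModel(
            name=self.name,
            n=self.n,
            theta=theta,
            rhs=self.rhs,
            y0=self.y0,
            observables=self.observables,
            dosing_compartments=self.dosing_compartments,
            time_unit=self.time_unit,
            metadata=dict(self.metadata),
        )

    def observe(self, name: str, y: np.ndarray) -> np.ndarray:
        try:
            fn = self.observables[name]
        except KeyError:
            raise KeyError(
                f"model {self.name!r} has no observable {name!r}; "
                f"available: {sorted(self.observables)}"
            ) from None
        return fn(np.asarray(y), self.theta)


# ---------------------------------------------------------------------------
# toy one-compartment model (closed form available, used by the test oracles)

def _toy_rhs(t, y, th, u):
    return np.array([-th["ke"] * y[0] + u[0]])


def _make_toy_1cpt() -> PKPDModel:
    """Linear one-compartment model: bolus D gives C(t) = D/V * exp(-ke*t)."""
    theta = {"V": 1.0, "ke": 0.1}
    return PKPDModel(
        name="toy_1cpt",
        n=1,
        theta=theta,
        rhs=_toy_rhs,
        y0=lambda th: np.zeros(1),
        observables={"C": lambda y, th: y[..., 0] / th["V"]},
        dosing_compartments=frozenset({1}),
        time_unit="hour",
    )


# ---------------------------------------------------------------------------
# tumor growth inhibition + myelosuppression
#
# State layout (time in days):
#   0  A     drug amount in central compartment, C = A/V
#   1  P     proliferating tumor cells
#   2..4     damaged tumor cells in a 3-stage death transit chain
#   5  Prol  proliferating neutrophil precursors
#   6..8     maturation transit compartments
#   9  Circ  circulating neutrophils N  [1e9/L]
#
# Tumor weight W = P + sum(damaged).  Untreated tumor switches smoothly from
# exponential (rate lam0) to linear (rate lam1) growth; drug kills
# proliferating cells at rate k2*C.  Neutrophils follow the transit-feedback
# model: drug inhibits precursor proliferation linearly (slope*C) and the
# feedback (Circ0/Circ)^gamma restores the baseline Circ0.

def _tumor_rhs(t, y, th, u):
    A, P, x2, x3, x4, prol, n1, n2, n3, circ = y
    C = A / th["V"]
    W = P + x2 + x3 + x4
    psi = th["psi"]
    growth = th["lam0"] * P / (1.0 + (th["lam0"] / th["lam1"] * W) ** psi) ** (1.0 / psi)
    kill = th["k2"] * C * P
    k1 = th["k1"]
    ktr = th["ktr"]
    circ_safe = max(circ, 1e-8)
    feedback = (th["Circ0"] / circ_safe) ** th["gamma"]
    edrug = th["slope"] * C
    return np.array(
        [
            -th["ke"] * A + u[0],
            growth - kill,
            kill - k1 * x2,
            k1 * (x2 - x3),
            k1 * (x3 - x4),
            ktr * prol * (1.0 - edrug) * feedback - ktr * prol,
            ktr * (prol - n1),
            ktr * (n1 - n2),
            ktr * (n2 - n3),
            ktr * (n3 - circ),
        ]
    )


def _tumor_y0(th):
    y = np.zeros(10)
    y[1] = th["w0"]
    y[5:10] = th["Circ0"]
    return y


def _make_tumor_myelo() -> PKPDModel:
    theta = {
        "V": 1.0,      # L (dose-normalized)
        "ke": 1.2,     # /day drug elimination
        "lam0": 0.30,  # /day exponential tumor growth
        "lam1": 0.80,  # mass/day linear tumor growth
        "psi": 20.0,   # growth-switch sharpness
        "k2": 0.05,    # /(conc*day) drug kill
        "k1": 0.50,    # /day death-transit rate
        "w0": 0.05,    # initial tumor weight
        "Circ0": 7.0,  # 1e9/L neutrophil baseline
        "ktr": 1.0,    # /day transit rate (4/MTT)
        "gamma": 0.17, # feedback exponent
        "slope": 0.015,  # /conc linear drug effect on precursors
    }
    W = lambda y, th: y[..., 1] + y[..., 2] + y[..., 3] + y[..., 4]
    return PKPDModel(
        name="tumor_myelo",
        n=10,
        theta=theta,
        rhs=_tumor_rhs,
        y0=_tumor_y0,
        observables={
            "C": lambda y, th: y[..., 0] / th["V"],
            "W": W,
            "N": lambda y, th: y[..., 9],
        },
        dosing_compartments=frozenset({1}),
        time_unit="day",
    )


# ---------------------------------------------------------------------------
# biomarker indirect response model
#
# An elevated biomarker B (baseline kin/kout = 15) is driven down towards the
# healthy target level B_tar = 10 by a drug that stimulates its loss:
#   dB/dt = kin - kout * (1 + Emax*C/(EC50+C)) * B
# One-compartment IV-bolus PK supplies C.

def _idr_rhs(t, y, th, u):
    A, B = y
    C = A / th["V"]
    stim = 1.0 + th["Emax"] * C / (th["EC50"] + C)
    return np.array([-th["ke"] * A + u[0], th["kin"] - th["kout"] * stim * B])


def _make_biomarker_idr() -> PKPDModel:
    theta = {
        "V": 1.0,    # L
        "ke": 0.5,   # /day
        "kin": 7.5,  # units/day production
        "kout": 0.5, # /day loss
        "Emax": 2.0, # max stimulation of loss
        "EC50": 5.0, # conc of half-max effect
    }
    return PKPDModel(
        name="biomarker_idr",
        n=2,
        theta=theta,
        rhs=_idr_rhs,
        y0=lambda th: np.array([0.0, th["kin"] / th["kout"]]),
        observables={
            "C": lambda y, th: y[..., 0] / th["V"],
            "B": lambda y, th: y[..., 1],
        },
        dosing_compartments=frozenset({1}),
        time_unit="day",
        metadata={"B_tar": 10.0},
    )


# ---------------------------------------------------------------------------
# antibiotic model with adaptive drug resistance
#
# Two-compartment PK (amounts per kg; C = A1/V1 in mg/L, time in hours)
# drives saturable bacterial kill; an adaptive-resistance state R in [0, 1]
# builds up with exposure and shifts the kill EC50 upward by (1 + beta*R):
#   dS/dt = kg*S*(1 - S/Smax) - kmax*C/(C + EC50*(1+beta*R)) * S
#   dR/dt = kon*C*(1 - R) - koff*R

def _abx_rhs(t, y, th, u):
    A1, A2, S, R = y
    V1 = th["V1"]
    C = A1 / V1
    k10 = th["CL"] / V1
    k12 = th["Q"] / V1
    k21 = th["Q"] / th["V2"]
    ec50 = th["EC50"] * (1.0 + th["beta"] * R)
    kill = th["kmax"] * C / (C + ec50)
    return np.array(
        [
            -(k10 + k12) * A1 + k21 * A2 + u[0],
            k12 * A1 - k21 * A2,
            (th["kg"] * (1.0 - S / th["Smax"]) - kill) * S,
            th["kon"] * C * (1.0 - R) - th["koff"] * R,
        ]
    )


def _make_antibiotic_ar() -> PKPDModel:
    theta = {
        "V1": 0.25,   # L/kg central volume
        "V2": 0.15,   # L/kg peripheral volume
        "CL": 0.10,   # L/h/kg clearance
        "Q": 0.05,    # L/h/kg inter-compartmental flow
        "kg": 0.8,    # /h bacterial growth rate
        "Smax": 1e8,  # CFU/mL carrying capacity
        "S0": 1e6,    # CFU/mL inoculum
        "kmax": 3.0,  # /h maximal kill rate
        "EC50": 4.0,  # mg/L kill EC50 (naive bacteria)
        "beta": 6.0,  # max EC50 shift from adaptive resistance
        "kon": 0.025, # /(mg/L * h) resistance onset
        "koff": 0.05, # /h resistance decay
    }
    return PKPDModel(
        name="antibiotic_ar",
        n=4,
        theta=theta,
        rhs=_abx_rhs,
        y0=lambda th: np.array([0.0, 0.0, th["S0"], 0.0]),
        observables={
            "C": lambda y, th: y[..., 0] / th["V1"],
            "S": lambda y, th: y[..., 2],
            "R": lambda y, th: y[..., 3],
        },
        dosing_compartments=frozenset({1}),
        time_unit="hour",
    )


_FACTORIES: dict[str, Callable[[], PKPDModel]] = {
    "toy_1cpt": _make_toy_1cpt,
    "tumor_myelo": _make_tumor_myelo,
    "biomarker_idr": _make_biomarker_idr,
    "antibiotic_ar": _make_antibiotic_ar,
}

EXAMPLE_MODELS = tuple(_FACTORIES)


def register_model(name: str, factory: Callable[[], PKPDModel]) -> None:
    """Register a user model factory under ``name``."""
    _FACTORIES[name] = factory


def build_example_model(name: str, **theta_overrides: float) -> PKPDModel:
    """Instantiate a registered model, optionally overriding parameters."""
    try:
        factory = _FACTORIES[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; available: {sorted(_FACTORIES)}"
        ) from None
    model = factory()
    if theta_overrides:
        model = model.with_theta(**theta_overrides)
    return model


def untreated_baseline(model: PKPDModel, t_grid: np.ndarray, **sim_opts):
    """Simulate the model with no drug administrations on ``t_grid``.

    Sanity check for feasible starting points: systems initialized at steady
    state (e.g. neutrophils at baseline) must stay constant, disease states
    evolve untreated.
    """
    from .dosing import DosingScenario
    from .simulate import simulate

    t_grid = np.asarray(t_grid, dtype=float)
    scenario = DosingScenario(
        records=(),
        t0=float(t_grid[0]),
        tf=float(t_grid[-1]),
        m=1,
        D_min=[0.0],
        D_max=[0.0],
        support_times=tuple(t_grid[1:-1]),
        time_unit=model.time_unit,
    )
    return simulate(model, [], scenario, **sim_opts)
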