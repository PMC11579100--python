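"""Bundled worked optimal-dosing problems.

Each example assembles a model, its dosing-record file and the study's cost
and state constraints into a ready-to-solve problem, together with sensible
defaults (feasible initial doses and a penalty-parameter schedule):

* ``tumor`` — minimize integrated tumor weight over days 12-32 while the
  neutrophil count stays above 1e9/L (path constraint), four dose groups of
  four daily IV boluses each.
* ``tumor_endpoint`` — additionally requires the neutrophils to have
  recovered to 3e9/L at the final time (point constraint).
* ``tumor_full`` — additionally limits mild neutropenia (N below 1.5) to at
  most 5 days (duration constraint).
* ``biomarker`` — return an elevated biomarker to the healthy target of 10
  within 14 days and keep it there (path constraint on [14, 42]), minimizing
  drug AUC; daily IV boluses with weekly dose changes (six groups).
* ``antibiotic_dose`` — twice-daily 1 h infusions of the same dose; keep
  the mean bacterial count over 6-24 h below 100 CFU/mL (mean-value
  constraint) with minimal drug AUC.
* ``antibiotic_interval`` — same model with the dose fixed at 50 mg/kg;
  optimize when the second infusion is administered.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .io_config import build_scenario, read_records
from .models import build_example_model
from .objectives import Constraint, ConstraintKind, CostFunctional, Direction
from .optimize import OCProblem

__all__ = ["EXAMPLES", "build_example_problem", "example_defaults"]

EXAMPLES = (
    "tumor",
    "tumor_endpoint",
    "tumor_full",
    "biomarker",
    "antibiotic_dose",
    "antibiotic_interval",
)


def _data_path(filename: str):
    return resources.files("optidose").joinpath("data", filename)


def _read(filename: str, **kw):
    with resources.as_file(_data_path(filename)) as p:
        return read_records(p, **kw)


def build_example_problem(name: str) -> OCProblem:
    if name.startswith("tumor"):
        model = build_example_model("tumor_myelo")
        recs = _read("tumor.csv")
        scenario = build_scenario(
            recs, m=4, D_min=np.zeros(4), D_max=np.full(4, 500.0), time_unit="day"
        )
        cost = CostFunctional(observable="W", window=(12.0, 32.0))
        constraints = [
            Constraint(
                name="neutropenia",
                kind=ConstraintKind.path,
                observable="N",
                direction=Direction.lower_bound,
                threshold=1.0,
                window=(12.0, 32.0),
            )
        ]
        if name in ("tumor_endpoint", "tumor_full"):
            constraints.append(
                Constraint(
                    name="recovery",
                    kind=ConstraintKind.point,
                    observable="N",
                    direction=Direction.lower_bound,
                    threshold=3.0,
                    window=(32.0, 32.0),
                )
            )
        if name == "tumor_full":
            constraints.append(
                Constraint(
                    name="mild_neutropenia_duration",
                    kind=ConstraintKind.duration,
                    observable="N",
                    direction=Direction.lower_bound,
                    threshold=0.0,
                    window=(0.0, 32.0),
                    sub_threshold=1.5,
                    max_duration=5.0,
                )
            )
        elif name not in ("tumor", "tumor_endpoint"):
            raise KeyError(f"unknown example {name!r}; available: {EXAMPLES}")
        return OCProblem(model, scenario, cost, tuple(constraints), name=name)

    if name == "biomarker":
        model = build_example_model("biomarker_idr")
        recs = _read("biomarker.csv")
        scenario = build_scenario(
            recs, m=6, D_min=np.zeros(6), D_max=np.full(6, 100.0), time_unit="day"
        )
        cost = CostFunctional(observable="C", window=(0.0, 42.0))
        constraint = Constraint(
            name="healthy_level",
            kind=ConstraintKind.path,
            observable="B",
            direction=Direction.upper_bound,
            threshold=model.metadata["B_tar"],
            window=(14.0, 42.0),
        )
        return OCProblem(model, scenario, cost, (constraint,), name=name)

    if name in ("antibiotic_dose", "antibiotic_interval"):
        model = build_example_model("antibiotic_ar")
        interval_mode = name == "antibiotic_interval"
        recs = _read(
            "antibiotic_interval.csv" if interval_mode else "antibiotic_dose.csv",
            infusion_durations={1: 1.0},  # 1 h IV infusion
        )
        if interval_mode:
            scenario = build_scenario(
                recs,
                m=1,
                D_min=[6.0],
                D_max=[23.0],
                mode="optimize_intervals",
                time_unit="hour",
            )
        else:
            scenario = build_scenario(
                recs, m=1, D_min=[0.0], D_max=[200.0], time_unit="hour"
            )
        cost = CostFunctional(observable="C", window=(0.0, 24.0))
        constraint = Constraint(
            name="bacterial_eradication",
            kind=ConstraintKind.mean_value,
            observable="S",
            direction=Direction.upper_bound,
            threshold=100.0,
            window=(6.0, 24.0),
        )
        return OCProblem(model, scenario, cost, (constraint,), name=name)

    raise KeyError(f"unknown example {name!r}; available: {EXAMPLES}")


def example_defaults(name: str) -> dict:
    """Feasible initial parameters and penalty schedule for each example."""
    defaults = {
        "tumor": {"D_init": np.full(4, 10.0), "rho_schedule": (10.0, 100.0, 1e3, 1e4)},
        "tumor_endpoint": {
            "D_init": np.full(4, 10.0),
            "rho_schedule": (1e4,),
        },
        "tumor_full": {
            "D_init": np.full(4, 10.0),
            "rho_schedule": ({"neutropenia": 1e4, "recovery": 1e4,
                              "mild_neutropenia_duration": 1e4},),
        },
        "biomarker": {
            "D_init": np.full(6, 6.0),
            "rho_schedule": (1.0, 100.0, 1e4, 1e6),
        },
        "antibiotic_dose": {
            "D_init": np.array([80.0]),
            "rho_schedule": (1e2, 1e4, 1e6),
        },
        "antibiotic_interval": {
            "D_init": np.array([10.0]),
            "rho_schedule": (1e2, 1e4),
        },
    }
    try:
        return defaults[name]
    except KeyError:
        raise KeyError(f"unknown example {name!r}; available: {EXAMPLES}") from None
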