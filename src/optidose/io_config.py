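"""Reading dosing-record CSVs and YAML problem configs; writing results.

The dosing-record dialect follows pharmacometric dataset conventions:
one row per event with columns ID, TIME, AMT, RATE, EVID, DV, CMT, DOSE_NR.
EVID=1 rows are administrations (RATE=-2 marks an infusion whose fixed
duration comes from the problem config), the EVID=0 row with the largest
TIME is a dummy observation marking the end of the horizon, and EVID=2 rows
are support points forced onto the integration grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .dosing import AdminKind, DoseRecord, DosingScenario, OptimizationMode
from .models import build_example_model
from .objectives import Constraint, CostFunctional, PenaltyConfig
from .optimize import OCProblem, SolveResult

__all__ = [
    "RecordSet",
    "read_records",
    "build_scenario",
    "ProblemConfig",
    "load_config",
    "save_config",
    "build_problem",
    "write_solution",
    "read_solution",
    "write_trace",
    "write_trajectory",
    "RecordParseError",
]

REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "RATE", "EVID", "DV", "CMT", "DOSE_NR"]


class RecordParseError(ValueError):
    """Malformed dosing-record file, with the offending row/column named."""


@dataclass
class RecordSet:
    """Parsed dosing-record file before scenario assembly."""

    records: tuple[DoseRecord, ...]
    tf: float
    support_times: tuple[float, ...] = ()


def read_records(
    path, infusion_durations: Mapping[int, float] | None = None
) -> RecordSet:
    """Parse a dosing-record CSV into dose records, final time and support
    points.  ``infusion_durations`` maps compartment -> fixed infusion
    duration for RATE=-2 rows (the control-file D1 analogue)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise RecordParseError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        warnings.warn(f"{path.name}: ignoring extra column(s) {extra}", stacklevel=2)
    for col in REQUIRED_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise RecordParseError(
                f"{path.name}: non-numeric value {df.loc[bad[0], col]!r} "
                f"in column {col}, row {bad[0] + 2}"
            )
        df[col] = numeric
    ids = df["ID"].dropna().unique()
    if len(ids) > 1:
        raise RecordParseError(f"{path.name}: multi-subject files not supported (IDs {ids})")

    obs = df[df["EVID"] == 0]
    if obs.empty:
        raise RecordParseError(f"{path.name}: no EVID=0 observation row marking tf")
    tf = float(obs["TIME"].max())
    support = tuple(float(t) for t in df.loc[df["EVID"] == 2, "TIME"])

    records = []
    durations = dict(infusion_durations or {})
    for idx, row in df[df["EVID"] == 1].iterrows():
        cmt = int(row["CMT"]) if np.isfinite(row["CMT"]) else 1
        rate = float(row["RATE"]) if np.isfinite(row["RATE"]) else 0.0
        if rate == -2.0:
            if cmt not in durations:
                raise RecordParseError(
                    f"{path.name}: row {idx + 2} is an infusion (RATE=-2) but no "
                    f"duration is configured for compartment {cmt}"
                )
            kind, duration = AdminKind.infusion, float(durations[cmt])
        elif rate == 0.0:
            kind, duration = AdminKind.bolus, None
        else:
            raise RecordParseError(
                f"{path.name}: row {idx + 2}: unsupported RATE {rate} "
                "(only 0 for bolus and -2 for fixed-duration infusion)"
            )
        group = int(row["DOSE_NR"]) if np.isfinite(row["DOSE_NR"]) and row["DOSE_NR"] > 0 else 1
        records.append(
            DoseRecord(
                time=float(row["TIME"]),
                amount=float(row["AMT"]),
                compartment=cmt,
                kind=kind,
                duration=duration,
                group=group,
            )
        )
    return RecordSet(records=tuple(records), tf=tf, support_times=support)


def build_scenario(
    recordset: RecordSet,
    m: int,
    D_min,
    D_max,
    t0: float = 0.0,
    mode: str | OptimizationMode = OptimizationMode.optimize_doses,
    time_unit: str = "day",
) -> DosingScenario:
    return DosingScenario(
        records=recordset.records,
        t0=t0,
        tf=recordset.tf,
        m=m,
        D_min=D_min,
        D_max=D_max,
        support_times=recordset.support_times,
        mode=OptimizationMode(mode),
        time_unit=time_unit,
    )


@dataclass
class ProblemConfig:
    """YAML-loadable problem definition (model, records file, cost,
    constraints, bounds, penalty schedule, solver settings)."""

    model: dict
    records: str
    cost: dict
    m: int
    D_min: list
    D_max: list
    D_init: list
    constraints: list = field(default_factory=list)
    mode: str = "optimize_doses"
    t0: float = 0.0
    time_unit: str = "day"
    infusion_durations: dict = field(default_factory=dict)
    penalty: dict = field(default_factory=lambda: {"rho": 1e4})
    simulation: dict = field(default_factory=dict)
    optimizer: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def load_config(path) -> ProblemConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        cfg = ProblemConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"{path.name}: bad config: {exc}") from None
    rec_path = (path.parent / cfg.records).resolve()
    if not rec_path.exists():
        raise FileNotFoundError(f"records file {rec_path} referenced by {path.name}")
    cfg.records = str(rec_path)
    return cfg


def save_config(cfg: ProblemConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def build_problem(cfg: ProblemConfig):
    """Assemble (OCProblem, PenaltyConfig, D_init, options) from a config."""
    model = build_example_model(cfg.model["name"], **cfg.model.get("theta", {}))
    durations = {int(k): float(v) for k, v in cfg.infusion_durations.items()}
    recordset = read_records(cfg.records, infusion_durations=durations)
    scenario = build_scenario(
        recordset,
        m=cfg.m,
        D_min=cfg.D_min,
        D_max=cfg.D_max,
        t0=cfg.t0,
        mode=cfg.mode,
        time_unit=cfg.time_unit,
    )
    cost = CostFunctional(
        observable=cfg.cost["observable"],
        window=tuple(cfg.cost["window"]),
        type=cfg.cost.get("type", "integral"),
    )
    constraints = tuple(
        Constraint(
            name=c["name"],
            kind=c["kind"],
            observable=c["observable"],
            direction=c.get("direction", "lower_bound"),
            threshold=float(c.get("threshold", 0.0)),
            window=tuple(c.get("window", (0.0, 0.0))),
            max_duration=c.get("max_duration"),
            sub_threshold=c.get("sub_threshold"),
            smoothing_eps=float(c.get("smoothing_eps", 0.0)),
        )
        for c in cfg.constraints
    )
    problem = OCProblem(
        model=model,
        scenario=scenario,
        cost=cost,
        constraints=constraints,
        name=cfg.model["name"],
    )
    penalty = PenaltyConfig(
        rho=cfg.penalty.get("rho", 1e4), schedule=cfg.penalty.get("schedule")
    )
    options = {"sim_opts": dict(cfg.simulation), **cfg.optimizer}
    return problem, penalty, np.asarray(cfg.D_init, dtype=float), options


# ---------------------------------------------------------------------------
# result output

def write_solution(result: SolveResult, path) -> None:
    """Full-precision solution JSON: doses, CFV, PFVs, margins, diagnostics."""
    bd = result.breakdown
    payload = {
        "D_star": [float(x) for x in result.D_star],
        "CFV": bd.CFV,
        "OFV": bd.OFV,
        "gradient_norm": result.gradient_norm,
        "n_evaluations": result.n_evaluations,
        "converged": result.converged,
        "feasible": result.feasible,
        "rho": result.rho if not isinstance(result.rho, Mapping) else dict(result.rho),
        "message": result.message,
    }
    if bd.PFV:
        payload["PFV"] = dict(bd.PFV)
        payload["PFV_over_rho"] = dict(bd.PFV_over_rho)
        payload["margins"] = dict(bd.margins)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_solution(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_trace(result: SolveResult, path) -> None:
    """One CSV row per outer optimizer iteration (D, CFV, PFVs, OFV, grad)."""
    rows = []
    for it, entry in enumerate(result.trace):
        row = {"iteration": it}
        for j, d in enumerate(entry["D"]):
            row[f"D{j + 1}"] = d
        row["CFV"] = entry["CFV"]
        for name, p in entry["PFV"].items():
            row[f"PFV_{name}"] = p
        row["OFV"] = entry["OFV"]
        row["grad_norm"] = entry["grad_norm"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_trajectory(traj, path) -> None:
    """Tidy CSV of the dense trajectory (TIME, states, observables)."""
    traj.to_frame().to_csv(path, index=False)
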