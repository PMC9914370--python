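"""Result serialization: trajectories and sweeps as CSV, summaries as JSON.

Every output written through :func:`write_results` gets a JSON metadata
sidecar (``<name>.meta.json``) recording the parameter set, schedule,
solver options, seed and package version, so a run can be reproduced from
its outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .model import STATE_NAMES, State
from .params import ParameterSet
from .sensitivity import PRCCResult
from .simulate import Trajectory

__all__ = [
    "write_trajectory_csv", "read_trajectory_csv", "write_sweep_csv",
    "write_prcc_csv", "write_scenario_json", "write_results",
]

TRAJECTORY_HEADER = ["day", *STATE_NAMES]


def _fmt(x: float) -> str:
    """Full double precision (17 significant digits)."""
    return f"{x:.17g}"


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """One row per grid day, header ``day,Tu,Ti,V,X,Y,C,W,Z,N``."""
    lines = [",".join(TRAJECTORY_HEADER)]
    for day, state in zip(traj.days, traj.states):
        lines.append(",".join(_fmt(v) for v in (day, *state)))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if list(frame.columns) != TRAJECTORY_HEADER:
        raise ValueError(f"unexpected trajectory header in {path}: {list(frame.columns)}")
    return frame


def write_sweep_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Sweep table with header ``param,value,Tu_day18``."""
    table.to_csv(path, index=False, float_format="%.17g")


def write_prcc_csv(result: PRCCResult, path: str | Path) -> None:
    """PRCC report with header ``parameter,prcc,significant``."""
    result.to_frame().to_csv(path, index=False, float_format="%.17g")


def write_scenario_json(states_by_day: Mapping[float, State], path: str | Path) -> None:
    """Scenario summary keyed by report day with all nine components."""
    payload = {
        _fmt(day): {name: float(v) for name, v in zip(STATE_NAMES, state)}
        for day, state in states_by_day.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_metadata(path: str | Path, *, params: ParameterSet | None = None,
                   schedule=None, solver_opts: Mapping | None = None,
                   seed: int | None = None, extra: Mapping | None = None) -> None:
    """JSON sidecar describing how an output was produced."""
    from . import __version__

    record: dict[str, Any] = {"software": "ovct", "version": __version__}
    if params is not None:
        record["parameters"] = params.as_dict()
    if schedule is not None:
        record["schedule"] = _jsonable(schedule)
    if solver_opts is not None:
        record["solver_opts"] = _jsonable(solver_opts)
    if seed is not None:
        record["seed"] = seed
    if extra:
        record.update(_jsonable(extra))
    Path(path).write_text(json.dumps(record, indent=2) + "\n")


def write_results(result, path: str | Path, *, params: ParameterSet | None = None,
                  schedule=None, solver_opts: Mapping | None = None,
                  seed: int | None = None) -> None:
    """Dispatch on result type and write the matching format plus sidecar."""
    path = Path(path)
    try:
        if isinstance(result, Trajectory):
            write_trajectory_csv(result, path)
            schedule = schedule or result.schedule
            solver_opts = solver_opts or result.stats
        elif isinstance(result, PRCCResult):
            write_prcc_csv(result, path)
            seed = seed if seed is not None else result.seed
        elif isinstance(result, pd.DataFrame):
            write_sweep_csv(result, path)
        elif isinstance(result, Mapping):
            write_scenario_json(result, path)
        else:
            raise TypeError(f"cannot serialize result of type {type(result).__name__}")
    except OSError as exc:
        raise OSError(f"failed writing results to {path}: {exc}") from exc
    write_metadata(path.with_suffix(path.suffix + ".meta.json"),
                   params=params, schedule=schedule,
                   solver_opts=solver_opts, seed=seed)
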