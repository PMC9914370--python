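"""Named treatment scenarios, dose/blockade sweeps, and threshold searches.

The three validation arms mirror the murine melanoma experiment the model
was calibrated against: carrier fluid only (``mock``), intratumoral
oncolytic virus at 2x10^6 PFU/day (``ov``), and the same viral dose
combined with CTLA-4 blockade at fraction 0.76 (``ov_actla4``), each given
for five consecutive days starting on day 8 post-implantation.  "Tumor
size" in every sweep report means the susceptible compartment ``Tu`` only,
matching how treatment outcomes are quoted (eradication = fewer than one
susceptible cell on the evaluation day).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .model import DEFAULT_INITIAL_STATE, State, TREATMENT_START_DAY, TreatmentSchedule
from .params import ConfigError, PARAM_NAMES, ParameterSet
from .simulate import Trajectory, simulate

__all__ = [
    "Scenario", "BUILTIN_ARMS", "run_scenario", "dose_sweep", "blockade_sweep",
    "parameter_response", "eradication_search", "cells_to_mm3", "mm3_to_cells",
]

#: cell count <-> volume conversion: 1 cm^3 of tumor ~ 10^9 cells,
#: hence 1 mm^3 ~ 10^6 cells.
CELLS_PER_MM3 = 1e6

#: (s, u) of the three built-in treatment arms.
BUILTIN_ARMS: dict[str, tuple[float, float]] = {
    "mock": (0.0, 0.0),
    "ov": (2e6, 0.0),
    "ov_actla4": (2e6, 0.76),
}

DEFAULT_TREATMENT_DURATION = 5.0


def cells_to_mm3(cells: float) -> float:
    """Convert a tumor cell count to an equivalent volume in mm^3."""
    return cells / CELLS_PER_MM3


def mm3_to_cells(volume_mm3: float) -> float:
    """Convert a tumor volume in mm^3 to an equivalent cell count."""
    return volume_mm3 * CELLS_PER_MM3


@dataclass(frozen=True)
class Scenario:
    """One named treatment setting: schedule, parameter overrides, report days."""

    name: str = "mock"
    schedule: TreatmentSchedule = field(
        default_factory=lambda: TreatmentSchedule(0.0, 0.0))
    overrides: Mapping[str, float] = field(default_factory=dict)
    report_days: tuple[float, ...] = (18.0,)

    def __post_init__(self) -> None:
        unknown = set(self.overrides) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameter name(s) in overrides: {sorted(unknown)}")
        object.__setattr__(self, "report_days", tuple(float(d) for d in self.report_days))
        if not self.report_days:
            raise ConfigError("at least one report day is required")

    @classmethod
    def builtin(cls, name: str, report_days: Sequence[float] = (18.0,),
                overrides: Mapping[str, float] | None = None) -> "Scenario":
        """One of the named arms: ``mock``, ``ov`` or ``ov_actla4``."""
        if name not in BUILTIN_ARMS:
            raise ConfigError(
                f"unknown scenario {name!r}; choose from {sorted(BUILTIN_ARMS)}")
        s, u = BUILTIN_ARMS[name]
        schedule = TreatmentSchedule(
            s_dose=s, u_block=u,
            start_day=TREATMENT_START_DAY, duration=DEFAULT_TREATMENT_DURATION)
        return cls(name=name, schedule=schedule,
                   overrides=dict(overrides or {}), report_days=tuple(report_days))


def _simulate_scenario(scenario: Scenario, params: ParameterSet | None = None,
                       **solver_opts) -> Trajectory:
    params = (params or ParameterSet()).replace(**dict(scenario.overrides))
    end_day = max(scenario.report_days)
    return simulate(
        params, scenario.schedule, DEFAULT_INITIAL_STATE,
        start_day=TREATMENT_START_DAY, end_day=end_day,
        extra_days=scenario.report_days, **solver_opts)


def run_scenario(scenario: Scenario | str, params: ParameterSet | None = None,
                 **solver_opts) -> dict[float, State]:
    """Simulate one scenario and return the state at each report day.

    ``scenario`` may be a built-in arm name or a full :class:`Scenario`.
    Integration always starts on day 8 post-implantation from the standard
    initial state.
    """
    if isinstance(scenario, str):
        scenario = Scenario.builtin(scenario)
    traj = _simulate_scenario(scenario, params, **solver_opts)
    return {day: traj.state_at(day) for day in scenario.report_days}


def _combined_arm_tu(s: float, u: float, overrides: Mapping[str, float],
                     day: float, params: ParameterSet | None, **solver_opts) -> float:
    schedule = TreatmentSchedule(s_dose=s, u_block=u,
                                 start_day=TREATMENT_START_DAY,
                                 duration=DEFAULT_TREATMENT_DURATION)
    scenario = Scenario(name="custom", schedule=schedule,
                        overrides=dict(overrides), report_days=(day,))
    traj = _simulate_scenario(scenario, params, **solver_opts)
    return traj.state_at(day).Tu


def dose_sweep(s_values: Sequence[float], u_fixed: float = 0.76, *,
               day: float = 18.0, params: ParameterSet | None = None,
               **solver_opts) -> pd.DataFrame:
    """Day-18 susceptible tumor size as a function of the OV dose rate.

    One full simulation per dose, everything else at baseline.  Returns a
    DataFrame with columns ``param, value, Tu_day18``.
    """
    rows = [("s", float(s), _combined_arm_tu(float(s), u_fixed, {}, day, params,
                                             **solver_opts))
            for s in s_values]
    return pd.DataFrame(rows, columns=["param", "value", "Tu_day18"])


def blockade_sweep(u_values: Sequence[float], s_fixed: float = 2e6, *,
                   day: float = 18.0, params: ParameterSet | None = None,
                   **solver_opts) -> pd.DataFrame:
    """Day-18 susceptible tumor size as a function of the CTLA-4 blockade rate."""
    rows = [("u", float(u), _combined_arm_tu(s_fixed, float(u), {}, day, params,
                                             **solver_opts))
            for u in u_values]
    return pd.DataFrame(rows, columns=["param", "value", "Tu_day18"])


def parameter_response(param_name: str, values: Sequence[float],
                       scenario: Scenario | str = "ov_actla4", *,
                       day: float = 18.0, params: ParameterSet | None = None,
                       **solver_opts) -> pd.DataFrame:
    """Day-18 susceptible tumor size as one model parameter is varied.

    Each run uses the combined-therapy schedule (unless another scenario is
    given) with only ``param_name`` changed from baseline.
    """
    if param_name not in PARAM_NAMES:
        raise ConfigError(f"unknown parameter name: {param_name!r}")
    if isinstance(scenario, str):
        scenario = Scenario.builtin(scenario, report_days=(day,))
    rows = []
    for v in values:
        overrides = dict(scenario.overrides)
        overrides[param_name] = float(v)
        tu = _combined_arm_tu(scenario.schedule.s_dose, scenario.schedule.u_block,
                              overrides, day, params, **solver_opts)
        rows.append((param_name, float(v), tu))
    return pd.DataFrame(rows, columns=["param", "value", "Tu_day18"])


class BracketError(ValueError):
    """The search bracket does not straddle the eradication boundary."""


def eradication_search(free: str, fixed_value: float,
                       bounds: tuple[float, float], tol: float = 1e-4, *,
                       day: float = 18.0, params: ParameterSet | None = None,
                       **solver_opts) -> float:
    """Bisect for the minimal dose (``free="s"``) or blockade (``free="u"``)
    eradicating the tumor by ``day``.

    Eradication means fewer than one susceptible tumor cell.  The lower
    bound must fail to eradicate and the upper bound must eradicate;
    bisection stops at relative tolerance ``tol`` on the free variable.
    """
    if free not in ("s", "u"):
        raise ConfigError(f"free variable must be 's' or 'u', got {free!r}")
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise BracketError(f"bounds must be increasing, got {bounds}")

    def eradicates(v: float) -> bool:
        s, u = (v, fixed_value) if free == "s" else (fixed_value, v)
        return _combined_arm_tu(s, u, {}, day, params, **solver_opts) < 1.0

    if eradicates(lo) or not eradicates(hi):
        raise BracketError(
            f"no eradication boundary in [{lo}, {hi}] for free variable {free!r}")
    while (hi - lo) > tol * max(abs(hi), 1e-300):
        mid = 0.5 * (lo + hi)
        if eradicates(mid):
            hi = mid
        else:
            lo = mid
    return hi
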