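"""File-driven run configuration.

Configs are flat ``key: value`` text files.  Recognized keys are the run
controls below; any other key must be an ASCII parameter name (``r_u``,
``delta_c``, ``gamma_c``, ...) and is treated as a baseline override.
An empty config reproduces the validation setting: baseline parameters,
mock arm, report day 18.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .experiments import BUILTIN_ARMS, DEFAULT_TREATMENT_DURATION, Scenario
from .model import TREATMENT_START_DAY, TreatmentSchedule
from .params import ConfigError, PARAM_NAMES, ParameterSet, parse_kv_file
from .simulate import DEFAULT_ATOL, DEFAULT_RTOL

__all__ = ["RunConfig", "load_config"]

_RUN_KEYS = {
    "scenario": str,
    "s": float,
    "u": float,
    "start_day": float,
    "duration": float,
    "report_days": str,
    "rtol": float,
    "atol": float,
    "method": str,
    "seed": int,
}


@dataclass(frozen=True)
class RunConfig:
    """A fully specified simulation run."""

    scenario: str = "mock"
    s: float | None = None                 # None -> the scenario arm's dose
    u: float | None = None
    start_day: float = TREATMENT_START_DAY
    duration: float = DEFAULT_TREATMENT_DURATION
    report_days: tuple[float, ...] = (18.0,)
    rtol: float = DEFAULT_RTOL
    atol: float = DEFAULT_ATOL
    method: str = "BDF"
    seed: int = 0
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in BUILTIN_ARMS and self.scenario != "custom":
            raise ConfigError(
                f"unknown scenario {self.scenario!r}; choose from "
                f"{sorted(BUILTIN_ARMS) + ['custom']}")
        if self.u is not None and not 0.0 <= self.u <= 1.0:
            raise ConfigError(f"u must be in [0, 1], got {self.u}")
        if self.s is not None and self.s < 0:
            raise ConfigError(f"s must be >= 0, got {self.s}")
        if self.rtol <= 0 or self.atol <= 0:
            raise ConfigError("solver tolerances must be > 0")
        if not self.report_days:
            raise ConfigError("at least one report day is required")
        unknown = set(self.overrides) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameter name(s): {sorted(unknown)}")

    def parameters(self) -> ParameterSet:
        return ParameterSet().replace(**self.overrides)

    def schedule(self) -> TreatmentSchedule:
        base_s, base_u = BUILTIN_ARMS.get(self.scenario, (0.0, 0.0))
        return TreatmentSchedule(
            s_dose=self.s if self.s is not None else base_s,
            u_block=self.u if self.u is not None else base_u,
            start_day=self.start_day, duration=self.duration)

    def to_scenario(self) -> Scenario:
        return Scenario(name=self.scenario, schedule=self.schedule(),
                        overrides=dict(self.overrides),
                        report_days=self.report_days)

    def solver_opts(self) -> dict:
        return {"rtol": self.rtol, "atol": self.atol, "method": self.method}

    # -- serialization --------------------------------------------------------

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"scenario: {self.scenario}",
            f"start_day: {self.start_day!r}",
            f"duration: {self.duration!r}",
            f"report_days: {','.join(repr(d) for d in self.report_days)}",
            f"rtol: {self.rtol!r}",
            f"atol: {self.atol!r}",
            f"method: {self.method}",
            f"seed: {self.seed}",
        ]
        if self.s is not None:
            lines.append(f"s: {self.s!r}")
        if self.u is not None:
            lines.append(f"u: {self.u!r}")
        lines.extend(f"{k}: {v!r}" for k, v in sorted(self.overrides.items()))
        Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a flat key:value run configuration."""
    raw = parse_kv_file(path)
    kwargs: dict = {}
    overrides: dict[str, float] = {}
    for key, value in raw.items():
        if key in _RUN_KEYS:
            caster = _RUN_KEYS[key]
            try:
                kwargs[key] = caster(value)
            except ValueError as exc:
                raise ConfigError(f"{path}: bad value for {key!r}: {value!r}") from exc
        elif key in PARAM_NAMES:
            try:
                overrides[key] = float(value)
            except ValueError as exc:
                raise ConfigError(f"{path}: bad value for {key!r}: {value!r}") from exc
        else:
            raise ConfigError(f"{path}: unknown key {key!r}")
    if "report_days" in kwargs:
        try:
            kwargs["report_days"] = tuple(
                float(d) for d in kwargs["report_days"].split(",") if d.strip())
        except ValueError as exc:
            raise ConfigError(f"{path}: bad report_days list") from exc
    return RunConfig(overrides=overrides, **kwargs)
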