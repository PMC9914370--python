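"""Model parameters: baseline values, plausible ranges, and config I/O.

All 45 rate constants of the tumor--immune model live here under ASCII
names (``delta_c`` for the cytokine kill rate, ``gamma_c`` for the cytokine
decay rate, and so on).  Each parameter carries an optional literature
(low, high) range; parameters reported as a single point value get a
default sampling interval of (baseline/10, 2*baseline) when used in global
sensitivity analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterator


class ConfigError(ValueError):
    """Raised for malformed or out-of-range configuration input."""


# name -> (baseline, range or None, units, description)
_PARAM_TABLE: dict[str, tuple[float, tuple[float, float] | None, str, str]] = {
    "r_u": (0.924, (0.12, 1.2), "1/day", "uninfected tumor growth rate"),
    "K_t": (3.3e9, (1e8, 9.7e9), "cells", "tumor carrying capacity"),
    "beta_t": (0.0038, None, "cells/(PFU day)", "viral infection rate of tumor cells"),
    "m_v": (1.0, None, "cells", "half-saturation constant of viral infection"),
    "delta_c": (0.2, None, "cells/(day pg/mL)", "tumor kill rate by cytokines"),
    "m_t": (1e5, None, "cells", "half-saturation constant of cytokine killing"),
    "delta_x": (2.0, (0.0096, 4.8), "1/day", "tumor lysis rate by CD8+ T cells"),
    "m_x": (1e3, None, "cells", "half-saturation constant of CD8+ killing"),
    "d_u": (8.68e-10, None, "1/(cell day)", "NK kill rate of uninfected tumor cells"),
    "r_i": (0.924, (0.12, 1.2), "1/day", "infected tumor growth rate"),
    "a_t": (1.0, (0.5, 2.6667), "1/day", "death rate of infected tumor cells"),
    "delta_z": (1.0, (0.0096, 4.8), "1/(cell day)", "infected-cell lysis by anti-viral cells"),
    "d_i": (8.68e-10, None, "1/(cell day)", "NK kill rate of infected tumor cells"),
    "b_t": (1949.0, (10.0, 1949.0), "PFU/cell", "viral burst size per lysed cell"),
    "gamma_v": (2.55, (0.024, 24.0), "1/day", "viral clearance rate"),
    "delta_v": (2.4e-4, (2.4e-5, 0.024), "1/(cell day)", "virus kill rate by anti-viral cells"),
    "d_v": (0.12, (0.024, 48.0), "1/(cell day)", "virion kill rate by NK cells"),
    "a_v": (2e-6, None, "1/(PFU day)", "T-cell recruitment rate via virus encounter"),
    "a_x": (0.0375, (2.4e-4, 2.4), "1/day", "CD8+ T-cell proliferation rate"),
    "h_x": (40.0, (40.0, 1e5), "cells", "half-saturation of CD8+ proliferation"),
    "gamma_x": (0.1, None, "1/day", "CD8+ T-cell death rate"),
    "nu": (1e-3, None, "1/molecule", "CTLA-4 inhibition measure on CD4+ activation"),
    "a_y": (0.09, (2.4e-4, 2.4), "cells/(day pg/mL)", "CD4+ (Th) proliferation rate"),
    "h_y": (1e3, (40.0, 1e5), "cells", "half-saturation of CD4+ proliferation"),
    "gamma_y": (0.1, None, "1/day", "CD4+ T-cell apoptosis rate"),
    "alpha_n": (0.4, None, "pg/mL/(cell^2 day)", "IFN-g production rate by NK cells"),
    "b_n": (1e-3, None, "1/molecule", "CTLA-4 inhibition of NK IFN-g output"),
    "alpha_x": (9.0, None, "pg/mL/(cell^2 day)", "IFN-g production rate by CD8+ T cells"),
    "b_x": (1e-3, None, "1/molecule", "CTLA-4 inhibition of CD8+ IFN-g output"),
    "alpha_y": (9.0, None, "pg/mL/(cell^2 day)", "IFN-g production rate by CD4+ T cells"),
    "b_y": (1e-3, None, "1/molecule", "CTLA-4 inhibition of CD4+ IFN-g output"),
    "gamma_c": (34.0, None, "1/day", "IFN-g decay rate"),
    "r_x": (800.0, (400.0, 800.0), "molecules/(cell day)", "CTLA-4 expression per CD8+ T cell"),
    "r_y": (5000.0, (2500.0, 5000.0), "molecules/(cell day)", "CTLA-4 expression per CD4+ T cell"),
    "gamma_w": (8.3178, None, "1/day", "CTLA-4 degradation rate"),
    "p_v": (0.6, (0.6, 2.5), "1/day", "anti-viral immune proliferation rate"),
    "gamma_z": (0.13296, None, "1/day", "anti-viral immune decay rate"),
    "s_n": (3.2e3, (3.2e3, 3.2e4), "cells/day", "constant NK influx"),
    "r_n": (1e-5, None, "1/day", "NK recruitment via immunogenic cell death"),
    "K_n": (6.63e10, None, "cells", "NK carrying capacity"),
    "m_n": (1e4, None, "cells", "half-saturation of NK recruitment"),
    "delta_n": (1e-7, None, "1/(cell day)", "NK inactivation rate by tumor cells"),
    "zeta": (0.5, None, "1/day", "NK stimulation rate by IFN-g"),
    "h_n": (3e2, None, "pg/mL", "half-saturation of cytokine NK stimulation"),
    "gamma_n": (4.12e-2, None, "1/day", "NK natural death rate"),
}

PARAM_NAMES: tuple[str, ...] = tuple(_PARAM_TABLE)

# half-saturation constants that must be strictly positive
_STRICTLY_POSITIVE = {"m_v", "m_t", "m_x", "h_x", "h_y", "m_n", "h_n", "K_t", "K_n"}


@dataclass(frozen=True)
class ParameterSet:
    """The full rate-constant set of the nine-compartment model.

    Defaults are the baseline literature values used for model validation.
    Instances are immutable; use :meth:`replace` for overrides.
    """

    r_u: float = 0.924
    K_t: float = 3.3e9
    beta_t: float = 0.0038
    m_v: float = 1.0
    delta_c: float = 0.2
    m_t: float = 1e5
    delta_x: float = 2.0
    m_x: float = 1e3
    d_u: float = 8.68e-10
    r_i: float = 0.924
    a_t: float = 1.0
    delta_z: float = 1.0
    d_i: float = 8.68e-10
    b_t: float = 1949.0
    gamma_v: float = 2.55
    delta_v: float = 2.4e-4
    d_v: float = 0.12
    a_v: float = 2e-6
    a_x: float = 0.0375
    h_x: float = 40.0
    gamma_x: float = 0.1
    nu: float = 1e-3
    a_y: float = 0.09
    h_y: float = 1e3
    gamma_y: float = 0.1
    alpha_n: float = 0.4
    b_n: float = 1e-3
    alpha_x: float = 9.0
    b_x: float = 1e-3
    alpha_y: float = 9.0
    b_y: float = 1e-3
    gamma_c: float = 34.0
    r_x: float = 800.0
    r_y: float = 5000.0
    gamma_w: float = 8.3178
    p_v: float = 0.6
    gamma_z: float = 0.13296
    s_n: float = 3.2e3
    r_n: float = 1e-5
    K_n: float = 6.63e10
    m_n: float = 1e4
    delta_n: float = 1e-7
    zeta: float = 0.5
    h_n: float = 3e2
    gamma_n: float = 4.12e-2

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, (int, float)):
                raise ConfigError(f"parameter {f.name} must be numeric, got {v!r}")
            if v < 0:
                raise ConfigError(f"parameter {f.name} must be >= 0, got {v}")
            if f.name in _STRICTLY_POSITIVE and v == 0:
                raise ConfigError(f"parameter {f.name} must be > 0")

    def replace(self, **overrides: float) -> "ParameterSet":
        """Return a copy with the named parameters replaced."""
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameter name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(self.as_dict().items())

    def content_hash(self) -> str:
        """Short stable identifier of the numeric content."""
        payload = ",".join(f"{k}={v!r}" for k, v in self.as_dict().items())
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @staticmethod
    def units(name: str) -> str:
        return _PARAM_TABLE[name][2]

    @staticmethod
    def description(name: str) -> str:
        return _PARAM_TABLE[name][3]

    @staticmethod
    def literature_range(name: str) -> tuple[float, float] | None:
        """The printed (low, high) interval, or None for point estimates."""
        return _PARAM_TABLE[name][1]

    def sampling_bounds(self, name: str) -> tuple[float, float]:
        """Sensitivity-analysis bounds for one parameter.

        The printed literature interval where one exists; otherwise
        one tenth to twice the current value.
        """
        rng = self.literature_range(name)
        if rng is not None:
            return rng
        v = float(getattr(self, name))
        if v == 0:
            raise ConfigError(
                f"parameter {name} has zero baseline and no literature range; "
                "exclude it from sampling"
            )
        return (v / 10.0, 2.0 * v)

    # -- flat key: value config serialization ---------------------------------

    def to_config(self, path: str | Path) -> None:
        """Write as plain-text ``name: value`` lines, one parameter per line."""
        lines = [f"{k}: {v!r}" for k, v in self.as_dict().items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_config(cls, path: str | Path) -> "ParameterSet":
        """Read a flat ``name: value`` file; unknown keys are rejected."""
        values = parse_kv_file(path)
        unknown = set(values) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in values.items()})


def parse_kv_file(path: str | Path) -> dict[str, str]:
    """Parse a ``key: value`` file, skipping blanks and ``#`` comments."""
    result: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
        key, _, value = line.partition(":")
        key = key.strip()
        if key in result:
            raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
        result[key] = value.strip()
    return result
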