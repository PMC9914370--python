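"""Core nine-compartment tumor--immune model.

State layout (units in parentheses):

======  =======================================================
``Tu``  susceptible (uninfected) tumor cells (cells)
``Ti``  virus-infected tumor cells (cells)
``V``   free oncolytic virions (PFU)
``X``   tumor-specific CD8+ T cells (cells)
``Y``   tumor-specific CD4+ T cells (cells)
``C``   tumor-suppressive cytokine IFN-g (pg/mL)
``W``   CTLA-4 molecules on activated T cells (molecules)
``Z``   anti-viral immune cells (cells)
``N``   natural killer cells (cells)
======  =======================================================

Susceptible tumor cells grow logistically and are killed by CD8+ T cells,
by IFN-g (the CD4+ arm acting through cytokines), and by NK cells.
Infection by free virions converts them to the infected compartment, whose
lysis releases new virions (burst size ``b_t``) and whose death via
immunogenic cell death recruits NK cells.  CTLA-4 (``W``) dampens CD4+
activation and cytokine production; the checkpoint antibody enters only as
the blockade fraction ``u`` scaling CTLA-4 expression, and the oncolytic
virus dose as the source rate ``s`` in the virion equation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .params import ParameterSet

STATE_NAMES: tuple[str, ...] = ("Tu", "Ti", "V", "X", "Y", "C", "W", "Z", "N")
N_STATES = len(STATE_NAMES)


class InvalidStateError(ValueError):
    """A state component is non-finite or impermissibly negative."""


class State(NamedTuple):
    """One point of the nine-compartment state space."""

    Tu: float
    Ti: float
    V: float
    X: float
    Y: float
    C: float
    W: float
    Z: float
    N: float

    def to_array(self) -> np.ndarray:
        return np.asarray(self, dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "State":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_STATES,):
            raise InvalidStateError(f"state must have {N_STATES} components, got shape {arr.shape}")
        return cls(*arr)

    def validate_initial(self, params: ParameterSet) -> None:
        """Check the admissibility constraints on an initial condition."""
        for name, v in zip(STATE_NAMES, self):
            if not math.isfinite(v):
                raise InvalidStateError(f"initial {name} is non-finite: {v}")
            if v < 0:
                raise InvalidStateError(f"initial {name} must be >= 0, got {v}")
        if self.Tu + self.Ti > params.K_t:
            raise InvalidStateError(
                f"initial tumor burden Tu+Ti={self.Tu + self.Ti:g} exceeds "
                f"carrying capacity K_t={params.K_t:g}"
            )


#: Initial condition used throughout the validation experiments: a 40 mm^3
#: tumor (4x10^7 cells) at treatment start, a small pre-existing adaptive
#: response (250 CD8+ and 250 CD4+ T cells) and 10^4 resident NK cells.
DEFAULT_INITIAL_STATE = State(Tu=4e7, Ti=0.0, V=0.0, X=250.0, Y=250.0,
                              C=0.0, W=0.0, Z=0.0, N=1e4)

#: Calendar day (post tumor implantation) on which therapy starts.
TREATMENT_START_DAY = 8.0


@dataclass(frozen=True)
class TreatmentSchedule:
    """Time-windowed therapy: OV dose rate ``s`` and CTLA-4 blockade ``u``.

    Both controls are constant on the half-open window
    ``[start_day, start_day + duration)`` and zero outside it, mirroring a
    course of daily injections represented as a continuous input.
    """

    s_dose: float = 0.0       # PFU/day while active
    u_block: float = 0.0      # dimensionless blockade fraction in [0, 1]
    start_day: float = TREATMENT_START_DAY
    duration: float = 5.0     # days

    def __post_init__(self) -> None:
        if self.s_dose < 0:
            raise ValueError(f"s_dose must be >= 0, got {self.s_dose}")
        if not 0.0 <= self.u_block <= 1.0:
            raise ValueError(f"u_block must be in [0, 1], got {self.u_block}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")

    @property
    def end_day(self) -> float:
        return self.start_day + self.duration

    def active(self, t: float) -> bool:
        return self.start_day <= t < self.end_day

    def controls_at(self, t: float) -> tuple[float, float]:
        """Effective (s, u) at calendar day ``t``."""
        if self.active(t):
            return self.s_dose, self.u_block
        return 0.0, 0.0


# Solver undershoot below this magnitude is clamped to zero inside the rate
# function; anything more negative is treated as a genuine failure.
NEGATIVITY_CLAMP = 1e-8
NEGATIVITY_HARD_LIMIT = NEGATIVITY_CLAMP * 1e3


def rhs(state, t: float, params: ParameterSet, schedule: TreatmentSchedule,
        *, cd8_self_renewal: bool = False) -> np.ndarray:
    """Instantaneous per-day rates of the nine compartments.

    Parameters
    ----------
    state : array-like of 9 floats or State
        Current state. Small negative values (stiff-solver undershoot within
        ``NEGATIVITY_CLAMP``) are treated as zero.
    t : float
        Calendar day; the schedule is evaluated here.
    cd8_self_renewal : bool
        Two readings of the CD8+ proliferation term circulate: a plain
        antigen-driven influx ``a_x (Tu+Ti)/(h_x+Tu+Ti)`` (default,
        ``False``) or the same term multiplied by ``X`` so expansion is
        proportional to the existing pool (``True``).  The influx form is
        the default because it is the one that reproduces the validation
        tumor burdens of the three treatment arms; the units of ``a_x``
        also fit it.
    """
    if t < 0:
        raise ValueError(f"t={t} precedes tumor implantation (day 0)")
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATES,):
        raise InvalidStateError(f"state must have {N_STATES} components, got shape {y.shape}")
    if not np.all(np.isfinite(y)):
        bad = STATE_NAMES[int(np.argmin(np.isfinite(y)))]
        raise InvalidStateError(f"non-finite state component {bad}")
    if np.any(y < -NEGATIVITY_HARD_LIMIT):
        bad = STATE_NAMES[int(np.argmin(y))]
        raise InvalidStateError(
            f"state component {bad} = {y[np.argmin(y)]:g} below the negativity tolerance"
        )
    y = np.where(y < 0.0, 0.0, y)
    Tu, Ti, V, X, Y, C, W, Z, N = y
    p = params
    s, u = schedule.controls_at(t)

    T = Tu + Ti
    crowding = 1.0 - T / p.K_t
    infection = p.beta_t * Tu / (p.m_v + Tu) * V
    cd8_kill = p.delta_x * X / (p.m_x + X)

    dTu = (p.r_u * Tu * crowding
           - infection
           - p.delta_c * Tu / (p.m_t + Tu) * C
           - cd8_kill * Tu
           - p.d_u * N * Tu)
    dTi = (p.r_i * Ti * crowding
           + infection
           - p.a_t * Ti
           - cd8_kill * Ti
           - p.delta_c * Ti / (p.m_t + Ti) * C
           - p.delta_z * Z * Ti
           - p.d_i * N * Ti)
    dV = p.b_t * p.a_t * Ti - p.delta_v * V * Z - p.gamma_v * V - p.d_v * N * V + s

    antigen_x = p.a_x * T / (p.h_x + T)
    dX = p.a_v * N * V + (antigen_x * X if cd8_self_renewal else antigen_x) - p.gamma_x * X

    ctla4_inhib = 1.0 + p.nu * W
    dY = (p.a_v * N * V / ctla4_inhib
          + p.a_y * T / ((p.h_y + T) * ctla4_inhib) * C
          - p.gamma_y * Y)
    dC = (p.alpha_n * T / (1.0 + p.b_n * W) * N
          + p.alpha_x * T / (1.0 + p.b_x * W) * X
          + p.alpha_y * T / (1.0 + p.b_y * W) * Y
          - p.gamma_c * C)
    dW = p.r_x * (1.0 - u) * X + p.r_y * (1.0 - u) * Y - p.gamma_w * W
    dZ = p.p_v * Ti - p.gamma_z * Z
    dN = (p.s_n
          + p.r_n * N * (1.0 - N / p.K_n) * (Ti / (Ti + p.m_n))
          + p.zeta * C * N / (C + p.h_n)
          - p.delta_n * T * N
          - p.gamma_n * N)

    out = np.array([dTu, dTi, dV, dX, dY, dC, dW, dZ, dN])
    if not np.all(np.isfinite(out)):
        bad = STATE_NAMES[int(np.argmin(np.isfinite(out)))]
        raise InvalidStateError(f"non-finite rate for component {bad}")
    return out


def tumor_free_equilibrium(params: ParameterSet) -> State:
    """The unique tumor-free steady state: everything zero except NK cells.

    With no tumor, virus, or adaptive response, NK influx balances NK death
    at N = s_n / gamma_n.
    """
    if params.gamma_n == 0:
        raise ZeroDivisionError("tumor-free equilibrium requires gamma_n > 0")
    n_bar = params.s_n / params.gamma_n
    return State(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, n_bar)


def tumor_free_stability(params: ParameterSet) -> dict[str, bool]:
    """Local stability conditions of the tumor-free equilibrium.

    The equilibrium is locally asymptotically stable when both tumor growth
    rates are dominated: ``r_u < d_u * N_bar`` (NK surveillance outpaces
    uninfected growth) and ``r_i < a_t`` (infected-cell death outpaces
    infected growth).  Comparisons are strict.
    """
    if params.gamma_n == 0:
        raise ZeroDivisionError("stability conditions require gamma_n > 0")
    n_bar = params.s_n / params.gamma_n
    cond_u = params.r_u < params.d_u * n_bar
    cond_i = params.r_i < params.a_t
    return {
        "stable": cond_u and cond_i,
        "condition_growth_u": cond_u,
        "condition_growth_i": cond_i,
    }
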