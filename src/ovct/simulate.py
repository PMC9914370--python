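"""Stiff integration of the tumor--immune system and day-indexed queries.

The system is stiff in the practical sense: compartments range from single
virions to ~10^9 tumor cells and the virion equation couples a burst term
of order 10^3 per lysed cell to clearance rates of order one.  The default
integrator is variable-order BDF with tight tolerances; the treatment
window boundary is an explicit breakpoint so the discontinuity in the dose
inputs never sits inside a solver step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    N_STATES,
    STATE_NAMES,
    State,
    TreatmentSchedule,
    InvalidStateError,
)
from .params import ParameterSet

__all__ = ["Trajectory", "IntegrationError", "simulate", "state_at", "eradicated"]

DEFAULT_RTOL = 1e-8
# Absolute tolerance is kept loose relative to the 1e9-cell tumor scale but
# tight against the sub-cell eradication regime; 1e-8 would force the BDF
# error control to resolve the initial cytokine transient below solver
# step-size limits.
DEFAULT_ATOL = 1e-6


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the failure time in ``failure_time``."""

    def __init__(self, message: str, failure_time: float | None = None):
        super().__init__(message)
        self.failure_time = failure_time


@dataclass
class Trajectory:
    """A single integration: time grid, state matrix, and dense interpolants."""

    days: np.ndarray                  # strictly increasing calendar days
    states: np.ndarray                # shape (len(days), 9)
    schedule: TreatmentSchedule
    params_hash: str
    stats: dict = field(default_factory=dict)
    _segments: list = field(default_factory=list, repr=False)  # (t0, t1, OdeSolution)

    @property
    def start_day(self) -> float:
        return float(self.days[0])

    @property
    def end_day(self) -> float:
        return float(self.days[-1])

    def state_at(self, day: float) -> State:
        """State at a calendar day, exact on grid points, dense elsewhere."""
        if not self.start_day <= day <= self.end_day:
            raise ValueError(
                f"day {day} outside trajectory range [{self.start_day}, {self.end_day}]"
            )
        # exact grid values take precedence over interpolation
        idx = np.searchsorted(self.days, day)
        if idx < len(self.days) and self.days[idx] == day:
            return State.from_array(self.states[idx])
        for t0, t1, sol in self._segments:
            if t0 <= day <= t1:
                return State.from_array(_sanitize(sol(day - t0)))
        raise ValueError(f"day {day} not covered by any integration segment")

    def eradicated(self, day: float) -> bool:
        """True when fewer than one susceptible tumor cell remains."""
        return bool(self.state_at(day).Tu < 1.0)

    def to_frame(self):
        """The trajectory as a pandas DataFrame with a ``day`` column."""
        import pandas as pd

        frame = pd.DataFrame(self.states, columns=list(STATE_NAMES))
        frame.insert(0, "day", self.days)
        return frame


def _sanitize(y: np.ndarray) -> np.ndarray:
    """Zero out solver undershoot below zero; reject non-finite values.

    Populations are nonnegative by model construction, but an accepted
    solver step may land a hair below zero when a compartment crashes
    through extinction (the virion population decays at up to ~1e6/day once
    dosing stops).  Those dips are integration noise with no model meaning
    and are reported as zero; genuinely pathological solutions surface as
    non-finite values, which are rejected.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        idx = int(np.argmin(np.isfinite(y)))
        raise InvalidStateError(
            f"non-finite trajectory component {STATE_NAMES[idx % N_STATES]}")
    return np.where(y < 0.0, 0.0, y)


def _rhs_factory(params: ParameterSet, s: float, u: float, cd8_self_renewal: bool):
    """Closure over plain floats for fast repeated evaluation.

    Clamping of sub-tolerance negative components matches the public
    :func:`ovct.model.rhs`; deep negativity aborts the step.
    """
    p = params
    (r_u, K_t, beta_t, m_v, delta_c, m_t, delta_x, m_x, d_u, r_i, a_t, delta_z,
     d_i, b_t, gamma_v, delta_v, d_v, a_v, a_x, h_x, gamma_x, nu, a_y, h_y,
     gamma_y, alpha_n, b_n, alpha_x, b_x, alpha_y, b_y, gamma_c, r_x, r_y,
     gamma_w, p_v, gamma_z, s_n, r_n, K_n, m_n, delta_n, zeta, h_n, gamma_n) = (
        p.r_u, p.K_t, p.beta_t, p.m_v, p.delta_c, p.m_t, p.delta_x, p.m_x,
        p.d_u, p.r_i, p.a_t, p.delta_z, p.d_i, p.b_t, p.gamma_v, p.delta_v,
        p.d_v, p.a_v, p.a_x, p.h_x, p.gamma_x, p.nu, p.a_y, p.h_y, p.gamma_y,
        p.alpha_n, p.b_n, p.alpha_x, p.b_x, p.alpha_y, p.b_y, p.gamma_c,
        p.r_x, p.r_y, p.gamma_w, p.p_v, p.gamma_z, p.s_n, p.r_n, p.K_n,
        p.m_n, p.delta_n, p.zeta, p.h_n, p.gamma_n)

    def f(t, y):
        Tu, Ti, V, X, Y, C, W, Z, N = (v if v > 0.0 else 0.0 for v in y)
        T = Tu + Ti
        crowding = 1.0 - T / K_t
        infection = beta_t * Tu / (m_v + Tu) * V
        cd8_kill = delta_x * X / (m_x + X)
        inhib = 1.0 + nu * W

        dTu = (r_u * Tu * crowding - infection
               - delta_c * Tu / (m_t + Tu) * C - cd8_kill * Tu - d_u * N * Tu)
        dTi = (r_i * Ti * crowding + infection - a_t * Ti - cd8_kill * Ti
               - delta_c * Ti / (m_t + Ti) * C - delta_z * Z * Ti - d_i * N * Ti)
        dV = b_t * a_t * Ti - delta_v * V * Z - gamma_v * V - d_v * N * V + s
        antigen_x = a_x * T / (h_x + T)
        dX = a_v * N * V + (antigen_x * X if cd8_self_renewal else antigen_x) - gamma_x * X
        dY = a_v * N * V / inhib + a_y * T / ((h_y + T) * inhib) * C - gamma_y * Y
        dC = (alpha_n * T / (1.0 + b_n * W) * N + alpha_x * T / (1.0 + b_x * W) * X
              + alpha_y * T / (1.0 + b_y * W) * Y - gamma_c * C)
        dW = r_x * (1.0 - u) * X + r_y * (1.0 - u) * Y - gamma_w * W
        dZ = p_v * Ti - gamma_z * Z
        dN = (s_n + r_n * N * (1.0 - N / K_n) * (Ti / (Ti + m_n))
              + zeta * C * N / (C + h_n) - delta_n * T * N - gamma_n * N)
        return (dTu, dTi, dV, dX, dY, dC, dW, dZ, dN)

    return f


def simulate(
    params: ParameterSet,
    schedule: TreatmentSchedule,
    init: State | Sequence[float] | None = None,
    start_day: float = 8.0,
    end_day: float = 18.0,
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "BDF",
    max_step: float = math.inf,
    first_step: float = 1e-10,
    cd8_self_renewal: bool = False,
    extra_days: Sequence[float] = (),
) -> Trajectory:
    """Integrate the model from ``start_day`` to ``end_day`` (calendar days).

    The trajectory's time grid contains every integer calendar day in range,
    the treatment window boundaries, and any ``extra_days`` requested; the
    dense solver output backs interpolation between grid points.

    ``first_step`` defaults to a very small value because the cytokine
    compartment has an enormous transient at the initial time (production
    rates of order 1e11/day against a zero initial concentration); left to
    its own heuristic the solver picks an initial step that underflows.

    Raises
    ------
    IntegrationError
        If the stiff solver fails (e.g. step-size underflow); the exception
        carries the failure time.
    """
    from .model import DEFAULT_INITIAL_STATE

    if init is None:
        init = DEFAULT_INITIAL_STATE
    if not isinstance(init, State):
        init = State.from_array(np.asarray(init, dtype=float))
    if end_day <= start_day:
        raise ValueError(f"end_day ({end_day}) must exceed start_day ({start_day})")
    init.validate_initial(params)

    # breakpoints: the schedule discontinuities inside the horizon
    cuts = {start_day, end_day}
    for b in (schedule.start_day, schedule.end_day):
        if start_day < b < end_day:
            cuts.add(float(b))
    breakpoints = sorted(cuts)

    grid = set(np.arange(math.ceil(start_day), math.floor(end_day) + 1, dtype=float))
    grid.update(breakpoints)
    grid.update(float(d) for d in extra_days)
    for d in extra_days:
        if not start_day <= d <= end_day:
            raise ValueError(f"extra day {d} outside [{start_day}, {end_day}]")
    all_days = np.array(sorted(grid))

    segments = []
    days_out: list[float] = []
    states_out: list[np.ndarray] = []
    y0 = init.to_array()
    nfev = njev = steps = 0
    for t0, t1 in zip(breakpoints[:-1], breakpoints[1:]):
        # controls are constant on each open sub-interval; sample the midpoint
        s_eff, u_eff = schedule.controls_at(0.5 * (t0 + t1))
        f = _rhs_factory(params, s_eff, u_eff, cd8_self_renewal)
        t_eval = all_days[(all_days >= t0) & (all_days <= t1)]
        # integrate in segment-local time: the system is autonomous within a
        # segment, and starting at 0 avoids the step-size floor eps*|t|
        sol = solve_ivp(
            f, (0.0, t1 - t0), y0, method=method, rtol=rtol, atol=atol,
            max_step=max_step, first_step=min(first_step, 0.5 * (t1 - t0)),
            dense_output=True, t_eval=t_eval - t0,
        )
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t0}, {t1}]: {sol.message}",
                failure_time=t0 + (sol.t[-1] if len(sol.t) else 0.0),
            )
        nfev += sol.nfev
        njev += sol.njev
        steps += len(sol.sol.ts) - 1 if sol.sol is not None else 0
        segments.append((t0, t1, sol.sol))
        start_idx = 1 if days_out else 0   # avoid duplicating the seam point
        days_out.extend(sol.t[start_idx:] + t0)
        states_out.extend(sol.y.T[start_idx:])
        y0 = sol.sol(t1 - t0)

    days = np.asarray(days_out)
    states = _sanitize(np.asarray(states_out))
    # exact pinning of the supplied initial state at the first grid point
    states[0] = init.to_array()
    return Trajectory(
        days=days,
        states=states,
        schedule=schedule,
        params_hash=params.content_hash(),
        stats={"nfev": nfev, "njev": njev, "steps": steps,
               "rtol": rtol, "atol": atol, "method": method},
        _segments=segments,
    )


def state_at(traj: Trajectory, day: float) -> State:
    """Module-level convenience for :meth:`Trajectory.state_at`."""
    return traj.state_at(day)


def eradicated(traj: Trajectory, day: float) -> bool:
    """True when the susceptible tumor burden is below one cell at ``day``."""
    return traj.eradicated(day)
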