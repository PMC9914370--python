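"""Global sensitivity analysis: Latin hypercube sampling and PRCC.

The analysis emulates a virtual cohort: each Latin-hypercube row is one
"mouse" with its own parameter set, simulated under a fixed therapy arm,
and the day-18 susceptible tumor burden is the output of interest.  Partial
rank correlation coefficients (PRCC) then measure the monotone association
between each parameter and the outcome while controlling for all other
sampled parameters.  A sampled *dummy* parameter with no model effect sets
the significance floor: parameters whose |PRCC| does not exceed the
dummy's are treated as indistinguishable from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc, rankdata

from .experiments import DEFAULT_TREATMENT_DURATION
from .model import DEFAULT_INITIAL_STATE, TREATMENT_START_DAY, TreatmentSchedule
from .params import ConfigError, PARAM_NAMES, ParameterSet
from .simulate import simulate

__all__ = ["LHSDesign", "PRCCResult", "lhs_sample", "prcc", "gsa_run",
           "GSA_SCENARIOS", "OV_PARAMETER_SUBSET", "DUMMY_NAME"]

DUMMY_NAME = "dummy"

#: Therapy controls (s, u) of each sensitivity scenario.
GSA_SCENARIOS: dict[str, tuple[float, float]] = {
    "ovt_only": (2e6, 0.0),
    "combined": (2e6, 0.76),
    "ov_params_only": (2e6, 0.76),
}

#: Parameters tied to the oncolytic virus itself: infection, burst,
#: clearance, immune recruitment by virions, and the anti-viral response.
OV_PARAMETER_SUBSET: tuple[str, ...] = (
    "b_t", "gamma_v", "delta_v", "d_v", "a_v",
    "beta_t", "m_v", "a_t", "p_v", "gamma_z",
)


@dataclass(frozen=True)
class LHSDesign:
    """A Latin hypercube over parameter ranges, plus the dummy column."""

    parameter_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    samples: np.ndarray            # shape (n, p)
    seed: int

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def p(self) -> int:
        return self.samples.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.samples[:, self.parameter_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(self.parameter_names))


@dataclass(frozen=True)
class PRCCResult:
    """Per-parameter partial rank correlation against the model output."""

    parameter_names: tuple[str, ...]     # excludes the dummy
    coefficients: np.ndarray             # aligned with parameter_names
    dummy_value: float
    endpoint_day: float
    scenario: str
    n_used: int
    n_dropped: int = 0
    seed: int | None = None

    @property
    def significant(self) -> np.ndarray:
        """|PRCC| strictly above the dummy's |PRCC|."""
        return np.abs(self.coefficients) > abs(self.dummy_value)

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.parameter_names.index(name)])

    def top(self, k: int) -> list[tuple[str, float]]:
        """The k parameters of largest |PRCC|, most influential first."""
        order = np.argsort(-np.abs(self.coefficients))[:k]
        return [(self.parameter_names[i], float(self.coefficients[i])) for i in order]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "parameter": list(self.parameter_names) + [DUMMY_NAME],
            "prcc": np.append(self.coefficients, self.dummy_value),
            "significant": np.append(self.significant, False),
        })
        return frame


def lhs_sample(bounds: Mapping[str, tuple[float, float]], n: int,
               seed: int) -> LHSDesign:
    """Seeded plain Latin hypercube over the given per-parameter intervals.

    Each column gets exactly one draw per equal-probability stratum (a
    random permutation of strata with uniform jitter inside each).  A
    ``dummy`` column on (0, 1) is appended automatically unless already
    present.
    """
    if n < 2:
        raise ConfigError(f"need at least 2 samples, got {n}")
    names = list(bounds)
    intervals = []
    for name in names:
        lo, hi = bounds[name]
        if not lo < hi:
            raise ConfigError(
                f"degenerate bounds for {name!r}: ({lo}, {hi}); "
                "exclude this parameter from sampling")
        intervals.append((float(lo), float(hi)))
    if DUMMY_NAME not in names:
        names.append(DUMMY_NAME)
        intervals.append((0.0, 1.0))
    lo = np.array([b[0] for b in intervals])
    hi = np.array([b[1] for b in intervals])
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    samples = qmc.scale(sampler.random(n), lo, hi)
    return LHSDesign(parameter_names=tuple(names), bounds=tuple(intervals),
                     samples=samples, seed=seed)


def _rank_residuals(ranks: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Residual of a rank vector after linear regression on other ranks."""
    design = np.column_stack([np.ones(len(ranks)), others])
    coef, *_ = np.linalg.lstsq(design, ranks, rcond=None)
    return ranks - design @ coef


def prcc(design: LHSDesign, outputs: Sequence[float], *,
         endpoint_day: float = 18.0, scenario: str = "custom",
         seed: int | None = None) -> PRCCResult:
    """Partial rank correlation of each sampled parameter with the output.

    For parameter j, both rank(x_j) and rank(y) are regressed on the ranks
    of all other columns (dummy included) and the Pearson correlation of
    the two residual vectors is the PRCC.  Ties receive average ranks.
    Rows with NaN output (failed simulations) are dropped listwise.
    """
    y = np.asarray(outputs, dtype=float)
    if y.shape != (design.n,):
        raise ConfigError(
            f"outputs length {y.shape} does not match design n={design.n}")
    keep = np.isfinite(y)
    n_dropped = int((~keep).sum())
    X = design.samples[keep]
    y = y[keep]
    n, p = X.shape
    if n <= p + 2:
        raise ConfigError(
            f"insufficient sample: n={n} rows for p={p} parameters (need n > p+2)")
    for j, name in enumerate(design.parameter_names):
        if np.all(X[:, j] == X[0, j]):
            raise ConfigError(f"column {name!r} is constant; cannot rank-correlate")

    rank_x = np.column_stack([rankdata(X[:, j]) for j in range(p)])
    rank_y = rankdata(y)

    coeffs = np.empty(p)
    for j in range(p):
        others = np.delete(rank_x, j, axis=1)
        rx = _rank_residuals(rank_x[:, j], others)
        ry = _rank_residuals(rank_y, others)
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        coeffs[j] = float(rx @ ry / denom) if denom > 0 else 0.0

    names = list(design.parameter_names)
    dummy_idx = names.index(DUMMY_NAME) if DUMMY_NAME in names else None
    if dummy_idx is None:
        raise ConfigError("design has no dummy column; build it with lhs_sample")
    model_names = tuple(nm for i, nm in enumerate(names) if i != dummy_idx)
    model_coeffs = np.delete(coeffs, dummy_idx)
    return PRCCResult(
        parameter_names=model_names, coefficients=model_coeffs,
        dummy_value=float(coeffs[dummy_idx]), endpoint_day=endpoint_day,
        scenario=scenario, n_used=n, n_dropped=n_dropped, seed=seed)


def gsa_bounds(varied: Sequence[str] | None = None,
               params: ParameterSet | None = None) -> dict[str, tuple[float, float]]:
    """Sampling intervals for the sensitivity analysis.

    Printed literature ranges where they exist, otherwise one tenth to
    twice the baseline value.
    """
    params = params or ParameterSet()
    names = list(varied) if varied is not None else list(PARAM_NAMES)
    return {name: params.sampling_bounds(name) for name in names}


# Failure budget: abort if more than this fraction of cohort rows fail.
MAX_FAILURE_FRACTION = 0.05

# GSA rows use a faster, slightly looser integration than the headline
# validation runs: rank statistics over a 500-mouse cohort are insensitive
# to the last solver digits, and extreme corner draws integrate far faster
# under LSODA.
GSA_SOLVER_OPTS = dict(method="LSODA", rtol=1e-6, atol=1e-6)


def gsa_run(scenario: str = "combined", n: int = 500, seed: int = 0, *,
            endpoint_day: float = 18.0, params: ParameterSet | None = None,
            solver_opts: dict | None = None) -> PRCCResult:
    """Run the full LHS + PRCC pipeline for one therapy scenario.

    ``ovt_only`` and ``combined`` vary every model parameter;
    ``ov_params_only`` varies only the virus-associated subset (all other
    parameters stay at baseline), emulating mice with identical tumors and
    immunity treated with viruses of differing character.
    """
    if scenario not in GSA_SCENARIOS:
        raise ConfigError(
            f"unknown GSA scenario {scenario!r}; choose from {sorted(GSA_SCENARIOS)}")
    params = params or ParameterSet()
    s, u = GSA_SCENARIOS[scenario]
    varied = OV_PARAMETER_SUBSET if scenario == "ov_params_only" else None
    design = lhs_sample(gsa_bounds(varied, params), n=n, seed=seed)
    schedule = TreatmentSchedule(s_dose=s, u_block=u,
                                 start_day=TREATMENT_START_DAY,
                                 duration=DEFAULT_TREATMENT_DURATION)
    opts = dict(GSA_SOLVER_OPTS)
    if solver_opts:
        opts.update(solver_opts)

    outputs = np.full(n, np.nan)
    failures = 0
    for i in range(n):
        row = {name: design.samples[i, j]
               for j, name in enumerate(design.parameter_names)
               if name != DUMMY_NAME}
        try:
            traj = simulate(params.replace(**row), schedule,
                            DEFAULT_INITIAL_STATE,
                            start_day=TREATMENT_START_DAY,
                            end_day=endpoint_day, **opts)
            outputs[i] = traj.state_at(endpoint_day).Tu
        except Exception:
            failures += 1
            if failures > MAX_FAILURE_FRACTION * n:
                raise RuntimeError(
                    f"more than {MAX_FAILURE_FRACTION:.0%} of cohort rows failed "
                    f"({failures}/{i + 1} so far) in scenario {scenario!r}")
    return prcc(design, outputs, endpoint_day=endpoint_day,
                scenario=scenario, seed=seed)
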