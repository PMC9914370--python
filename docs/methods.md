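# Methods

## Model and assumptions

The model tracks population-level interactions in the tumor
microenvironment of a murine melanoma under oncolytic virotherapy (OV) and
CTLA-4 blockade. Its principal assumptions:

- Both tumor compartments grow logistically against a shared carrying
  capacity `K_t`; infection converts susceptible to infected cells through
  a saturating contact term `beta_t*Tu/(m_v+Tu)*V`.
- Killing terms saturate in the killer population (CD8⁺ lysis,
  `delta_x*X/(m_x+X)`) or in the target population (cytokine killing,
  `delta_c*Tu/(m_t+Tu)*C`), reflecting limited effector capacity; NK
  killing is mass-action.
- CD8⁺ T cells kill directly; CD4⁺ T cells act only through the cytokine
  pool (IFN-γ). CTLA-4 (`W`) inhibits CD4⁺ activation and all three
  cytokine production channels via `1/(1+b·W)` factors, but not CD8⁺
  proliferation. The checkpoint antibody enters solely as the factor
  `(1-u)` on CTLA-4 expression.
- Virions are produced in bursts (`b_t` per lysed infected cell), cleared
  naturally, by anti-viral immunity, and by NK cells; NK clearance of
  virions (`d_v*N*V`) is the main obstacle to viral spread.
- NK cells have a constant tissue influx `s_n`, are recruited by
  immunogenic death of infected cells and by IFN-γ, and are inactivated by
  tumor contact.
- Treatment controls `s(t)` (PFU/day) and `u(t)` (dimensionless) are
  piecewise constant on the half-open window `[start_day, start_day +
  duration)` — a five-day daily-injection course represented as a
  continuous input. The day-30 regrowth endpoint confirms this reading:
  it is reproduced to 2e-5 relative only if both controls switch off at
  day 13.

Two readings of the CD8⁺ proliferation term circulate (with and without a
factor of `X`). The package implements both behind the
`cd8_self_renewal` switch and defaults to the plain antigen-driven influx
`a_x*(Tu+Ti)/(h_x+Tu+Ti)`: it reproduces the three calibration tumor
burdens to ≤0.3% while the `X`-proportional form misses them by 16–35%,
and the units of `a_x` (cell⁻¹ day⁻¹) fit the influx reading.

The tumor-free equilibrium `(0,...,0, s_n/gamma_n)` is checked by direct
substitution; its printed local-stability conditions (`r_u < d_u*N̄`,
`r_i < a_t`, strict comparisons) are implemented as condition checks, not
re-derived.

## Calendar and initial condition

Simulation time is calendar days post tumor implantation. Therapy starts
on day 8, when the tumor has reached `4e7` cells (40 mm³ at the 1 cm³ =
1e9 cells conversion). The standard initial state is
`(Tu, Ti, V, X, Y, C, W, Z, N) = (4e7, 0, 0, 250, 250, 0, 0, 0, 1e4)`:
a small pre-existing adaptive response and resident NK population, nothing
else. Endpoints are reported at day 18 (ten days of dynamics) and day 30.

## Numerical choices

- **Integrator.** `scipy.integrate.solve_ivp` with variable-order BDF,
  `rtol = 1e-8`, `atol = 1e-6`. The system is stiff: compartments span ten
  orders of magnitude and the virion equation couples a burst size of
  ~2×10³ to clearance rates up to ~10⁶/day. `atol = 1e-6` resolves the
  sub-cell eradication regime while leaving the error control workable
  during the initial cytokine transient (production of order 10¹¹
  pg/mL/day against a zero start); at `atol = 1e-8` BDF's error test
  forces steps below its floor. Endpoints are insensitive to `atol` over
  1e-8…1e-2 (identical to five digits).
- **Initial step.** The same transient defeats the solver's automatic
  initial-step heuristic, so integrations start with an explicit
  `first_step = 1e-10` days.
- **Segmented, local-time integration.** Each treatment-window boundary is
  a hard breakpoint; the system is autonomous within a segment, so every
  segment integrates from local time 0 (this also removes the `eps·|t|`
  step-size floor and makes time-translation invariance exact). Dense
  output per segment backs day queries; integer days and window boundaries
  are forced grid points.
- **Negativity.** Inside the rate function, components within `(-1e-8, 0)`
  are treated as zero (stiff-solver undershoot); values below `-1e-5`
  raise. Trajectory outputs clamp sub-zero undershoot to zero — an
  accepted step can land ~1e-3 below zero when the virion population
  crashes at ~10⁶/day after dosing stops, which is integration noise with
  no model meaning — and any non-finite value is an error.
- **Eradication.** Strictly fewer than one susceptible tumor cell at the
  evaluation day (`Tu < 1`); "tumor size" in all reports is the
  susceptible compartment only. The bisection threshold search assumes a
  monotone eradication boundary within the bracket, verified empirically
  over the dose and blockade grids.
- **Convergence evidence.** Day-18 endpoints are stable from `rtol 1e-8`
  through `1e-12` and agree with a high-order explicit method (DOP853) to
  1e-5 on a short horizon. Published near-threshold endpoints (e.g. the
  `u = 0.93` burden and the eradication-case residuals) differ from our
  converged values by 5–30%: these sit in a regime where the outcome is
  steeply amplified in the inputs (the blockade threshold moves the
  burden by five orders of magnitude over Δu ≈ 0.002), so small
  differences in the original solver's error are magnified. Our values at
  loose tolerances move toward the published ones, consistent with that
  reading; defaults stay at the tight setting.

## Sensitivity analysis

- **Design.** Plain seeded Latin hypercube (`scipy.stats.qmc`), one draw
  per equal-probability stratum per column, over all 45 model parameters
  plus a dummy column on (0,1); `n = 500` rows emulate a 500-mouse virtual
  cohort. Bounds are the printed literature intervals where one exists,
  otherwise one tenth to twice the baseline. The blockade fraction `u` is
  fixed by scenario, never sampled.
- **Scenarios.** `ovt_only` (s = 2e6, u = 0), `combined` (s = 2e6,
  u = 0.76) and `ov_params_only` — the combined arm with only the ten
  virus-associated parameters varied (`b_t, gamma_v, delta_v, d_v, a_v,
  beta_t, m_v, a_t, p_v, gamma_z`), a choice the analysis documents since
  no canonical list exists. Output is day-18 susceptible burden.
- **PRCC.** Rank-transform (average ranks on ties) all columns and the
  output; for each parameter regress its ranks and the output's ranks on
  all other columns and correlate the residuals. Rows whose simulation
  fails are dropped listwise (aborting if more than 5% fail). The dummy's
  |PRCC| is the significance floor. An independent cross-check —
  partial correlation via inversion of the rank correlation matrix —
  agrees to 1e-10.
- **Cohort solver.** GSA rows integrate with LSODA at `rtol = atol =
  1e-6`: rank statistics are insensitive to the last solver digits, and
  extreme corner draws (e.g. `d_v` up to 48, `gamma_v` down to 0.024)
  integrate several-fold faster. Headline endpoints always use the BDF
  defaults.
- **Interpretation limits.** PRCC magnitudes depend on the bound
  construction, which is under-specified for the 27 point-estimate
  parameters; signs and rankings of the dominant parameters are the
  robust output. Under our bounds, `delta_c` ranks sixth (PRCC ≈ −0.33)
  rather than fifth in the OVT-only analysis, swapped with `b_y` — the
  two sit within each other's sampling noise.

## What the cohort emulates — and does not

Each LHS row is a "mouse" differing only in rate constants; the initial
tumor, immune state and schedule are identical across the cohort. Real
cohorts also vary in initial burden, engraftment and measurement error,
none of which is modeled, so passing the structural GSA checks shows the
analysis machinery and the model's local sensitivities are right — not
that the model predicts inter-animal variability. The model itself is a
well-mixed population description: no spatial structure, no
pharmacokinetics of the antibody beyond `(1−u)`, no PD-1 pathway, no
T-cell exhaustion, and cytokine action collapsed onto a single IFN-γ
pool.

## Problem sizes

The full test suite runs three GSA scenarios at `n = 500` (≈1,500 ODE
solves, about two minutes) plus a few hundred fast deterministic runs;
`scripts/acceptance.py` performs twelve deterministic integrations and
completes in seconds.
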