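"""Unit tests for the model right-hand side, equilibrium, and parameters."""

import numpy as np
import pytest

from ovct import (
    DEFAULT_INITIAL_STATE,
    ConfigError,
    InvalidStateError,
    ParameterSet,
    State,
    TreatmentSchedule,
    rhs,
    tumor_free_equilibrium,
    tumor_free_stability,
)
from conftest import random_states_and_params
from oracles import rhs_reference

INACTIVE = TreatmentSchedule(0.0, 0.0, start_day=8.0, duration=5.0)
ZERO_STATE = State(*([0.0] * 9))


class TestRhs:
    def test_zero_state_inactive_schedule_only_nk_influx(self, baseline):
        """With nothing alive and no dosing, only the constant NK influx acts."""
        rates = rhs(ZERO_STATE, 20.0, baseline, INACTIVE)
        expected = np.zeros(9)
        expected[8] = 3.2e3  # s_n
        np.testing.assert_array_equal(rates, expected)

    def test_zero_state_active_schedule_source_terms_only(self, baseline):
        sched = TreatmentSchedule(2e6, 0.76, start_day=8.0, duration=5.0)
        rates = rhs(ZERO_STATE, 10.0, baseline, sched)
        expected = np.zeros(9)
        expected[2] = 2e6    # OV dose
        expected[8] = 3.2e3  # NK influx
        np.testing.assert_array_equal(rates, expected)

    def test_tumor_only_rate_matches_hand_computation(self, baseline):
        """dTu for the standard initial state, assembled term by term."""
        state = State(4e7, 0, 0, 250, 250, 0, 0, 0, 1e4)
        p = baseline
        logistic = p.r_u * 4e7 * (1 - 4e7 / p.K_t)
        cd8 = p.delta_x * 250 / (p.m_x + 250) * 4e7
        nk = p.d_u * 1e4 * 4e7
        expected = logistic - cd8 - nk
        got = rhs(state, 8.0, p, INACTIVE)[0]
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("cd8_self_renewal", [False, True])
    def test_matches_independent_term_by_term_oracle(self, rng, baseline,
                                                     cd8_self_renewal):
        """100 random states/parameter draws agree with the naive oracle."""
        sched = TreatmentSchedule(3e6, 0.4, start_day=8.0, duration=5.0)
        for state, params in random_states_and_params(rng, 100):
            t = float(rng.uniform(8.0, 20.0))
            s, u = sched.controls_at(t)
            expected = rhs_reference(state, params.as_dict(), s, u,
                                     cd8_self_renewal)
            got = rhs(state, t, params, sched,
                      cd8_self_renewal=cd8_self_renewal)
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=0)

    def test_small_negative_components_are_clamped(self, baseline):
        state = np.zeros(9)
        state[2] = -1e-9  # within solver-undershoot tolerance
        rates = rhs(state, 20.0, baseline, INACTIVE)
        assert rates[2] == 0.0

    def test_deeply_negative_component_rejected(self, baseline):
        state = np.zeros(9)
        state[0] = -1.0
        with pytest.raises(InvalidStateError, match="Tu"):
            rhs(state, 20.0, baseline, INACTIVE)

    def test_non_finite_component_rejected_by_name(self, baseline):
        state = np.zeros(9)
        state[4] = np.nan
        with pytest.raises(InvalidStateError, match="Y"):
            rhs(state, 20.0, baseline, INACTIVE)

    def test_time_before_implantation_rejected(self, baseline):
        with pytest.raises(ValueError, match="implantation"):
            rhs(ZERO_STATE, -1.0, baseline, INACTIVE)


class TestTreatmentSchedule:
    def test_window_is_half_open(self):
        sched = TreatmentSchedule(2e6, 0.76, start_day=8.0, duration=5.0)
        assert sched.controls_at(8.0) == (2e6, 0.76)
        assert sched.controls_at(12.999) == (2e6, 0.76)
        assert sched.controls_at(13.0) == (0.0, 0.0)
        assert sched.controls_at(7.999) == (0.0, 0.0)

    @pytest.mark.parametrize("kwargs", [
        dict(s_dose=-1.0), dict(u_block=1.5), dict(u_block=-0.1),
        dict(duration=-2.0),
    ])
    def test_invalid_schedule_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TreatmentSchedule(**{"s_dose": 0.0, "u_block": 0.0, **kwargs})


class TestScheduleProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    # dyadic grids keep the window arithmetic exact in floating point
    @given(start=st.integers(0, 400), duration=st.integers(0, 160),
           offset=st.integers(-40, 200))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_controls_follow_half_open_window(self, start, duration, offset):
        start, duration, offset = start / 8, duration / 8, offset / 8
        sched = TreatmentSchedule(1e6, 0.5, start_day=start, duration=duration)
        expected = (1e6, 0.5) if 0.0 <= offset < duration else (0.0, 0.0)
        assert sched.controls_at(start + offset) == expected


class TestEquilibrium:
    def test_nk_level_is_influx_over_death(self, baseline):
        e0 = tumor_free_equilibrium(baseline)
        assert e0.N == pytest.approx(3.2e3 / 4.12e-2, rel=1e-12)
        assert e0.N == pytest.approx(7.76699e4, rel=1e-5)
        assert all(v == 0.0 for v in e0[:-1])

    def test_zero_influx_gives_zero_state(self, baseline):
        e0 = tumor_free_equilibrium(baseline.replace(s_n=0.0))
        assert all(v == 0.0 for v in e0)

    def test_rhs_vanishes_at_equilibrium(self, baseline):
        e0 = tumor_free_equilibrium(baseline)
        rates = rhs(e0, 20.0, baseline, INACTIVE)
        scale = max(abs(v) for v in e0)
        assert np.max(np.abs(rates)) <= 1e-9 * scale

    def test_zero_nk_death_rate_rejected(self, baseline):
        with pytest.raises(ZeroDivisionError):
            tumor_free_equilibrium(baseline.replace(gamma_n=0.0))


class TestStability:
    def test_baseline_is_unstable_via_growth_condition(self, baseline):
        """NK surveillance (d_u*N_bar ~ 6.7e-5) cannot dominate r_u = 0.924."""
        result = tumor_free_stability(baseline)
        assert result["condition_growth_u"] is False
        assert result["condition_growth_i"] is True  # r_i = 0.924 < a_t = 1
        assert result["stable"] is False

    def test_zero_growth_rates_are_stable(self, baseline):
        result = tumor_free_stability(baseline.replace(r_u=0.0, r_i=0.0))
        assert result["stable"] is True

    def test_boundary_equality_counts_as_unstable(self, baseline):
        result = tumor_free_stability(baseline.replace(r_i=baseline.a_t))
        assert result["condition_growth_i"] is False


class TestParameterSet:
    def test_negative_value_rejected(self):
        with pytest.raises(ConfigError, match="r_u"):
            ParameterSet(r_u=-0.1)

    def test_zero_half_saturation_rejected(self):
        with pytest.raises(ConfigError, match="m_x"):
            ParameterSet(m_x=0.0)

    def test_unknown_override_rejected(self, baseline):
        with pytest.raises(ConfigError, match="not_a_param"):
            baseline.replace(not_a_param=1.0)

    def test_config_round_trip(self, baseline, tmp_path):
        modified = baseline.replace(gamma_c=68.0, d_v=0.5)
        path = tmp_path / "params.cfg"
        modified.to_config(path)
        assert ParameterSet.from_config(path) == modified

    def test_config_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("r_u: 0.9\nbogus_rate: 1.0\n")
        with pytest.raises(ConfigError, match="bogus_rate"):
            ParameterSet.from_config(path)

    def test_sampling_bounds_prefer_literature_range(self, baseline):
        assert baseline.sampling_bounds("delta_x") == (0.0096, 4.8)
        lo, hi = baseline.sampling_bounds("gamma_c")
        assert lo == pytest.approx(3.4) and hi == pytest.approx(68.0)

    def test_initial_state_respects_carrying_capacity(self, baseline):
        DEFAULT_INITIAL_STATE.validate_initial(baseline)
        over = State(3e9, 4e8, 0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(InvalidStateError, match="carrying capacity"):
            over.validate_initial(baseline)
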