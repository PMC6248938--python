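"""Closed-form MKM: protraction factor, survival, dose inversion, RBE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mkmrbe import (
    DeliverySchedule,
    MKMParameters,
    discrete_protraction_oracle,
    equivalent_instantaneous_dose,
    gamma_from_yd,
    lea_catcheside_factor,
    load_parameter_blocks,
    neg_log_survival,
    rbe,
    repair_rate_from_halftime,
)


class TestLeaCatcheside:
    def test_instantaneous_limit_is_one(self):
        assert lea_catcheside_factor(0.46, 0.0) == 1.0

    @pytest.mark.parametrize("duration, expected", [
        (1.0, 0.862804),      # closed form at a+c = 0.46/h, T = 1 h
        (1.0 / 12.0, 0.987301),  # T = 5 min
    ])
    def test_closed_form_values(self, duration, expected):
        # frozen from the discrete double-sum oracle at N = 1e5
        assert lea_catcheside_factor(0.46, duration) == pytest.approx(expected, abs=1e-4)

    def test_series_and_closed_form_agree_at_switch(self):
        # the series branch takes over below x = 1e-4; both forms must agree
        # to ~1e-12 on either side of the switch
        for x in (0.9e-4, 1.1e-4):
            series = 1.0 - x / 3.0 + x * x / 12.0
            closed = 2.0 / (x * x) * (x + math.expm1(-x))
            assert lea_catcheside_factor(1.0, x) == pytest.approx(series, abs=1e-11)
            assert series == pytest.approx(closed, abs=1e-11)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            lea_catcheside_factor(-0.5, 1.0)
        with pytest.raises(ValueError):
            lea_catcheside_factor(0.46, -1.0)
        with pytest.raises(ValueError, match="t_r"):
            lea_catcheside_factor(0.46, 5.0, t_r=4.0)

    @given(
        rate=st.floats(0.01, 10.0),
        t1=st.floats(0.001, 5.0),
        scale=st.floats(1.01, 3.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_strictly_decreasing_in_duration_and_rate(self, rate, t1, scale):
        f1 = lea_catcheside_factor(rate, t1)
        f2 = lea_catcheside_factor(rate, t1 * scale)
        f3 = lea_catcheside_factor(rate * scale, t1)
        assert 0.0 < f2 < f1 <= 1.0
        assert f3 < f1


class TestDiscreteOracle:
    @pytest.mark.parametrize("x", [0.01, 0.1, 0.46, 1.0, 5.0])
    def test_matches_closed_form_at_1e5_steps(self, x):
        # (a+c)*T = x with T = 1 h
        closed = lea_catcheside_factor(x, 1.0)
        discrete = discrete_protraction_oracle(x, 1.0, 10**5)
        assert discrete == pytest.approx(closed, rel=1e-3)

    def test_short_delivery_limit(self):
        assert discrete_protraction_oracle(0.46, 1e-9, 100) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_convergence_toward_closed_form(self):
        closed = lea_catcheside_factor(0.46, 1.0)
        errors = [
            abs(discrete_protraction_oracle(0.46, 1.0, n) - closed)
            for n in (2, 10, 100, 1000, 10**4)
        ]
        assert errors == sorted(errors, reverse=True)
        assert errors[-1] < 1e-4

    def test_rejects_tiny_step_count(self):
        with pytest.raises(ValueError):
            discrete_protraction_oracle(0.46, 1.0, 1)


class TestGammaCoupling:
    def test_cancellation_case(self):
        assert gamma_from_yd(math.pi, 1.0, 1.0) == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("yd, printed", [(2.32, 2.96), (2.34, 2.98)])
    def test_matches_printed_couplings(self, yd, printed):
        # NCI-H460 parameter table: gamma derived from the beam's y_D with
        # rho = 1 g/cm^3, r_d = 0.5 um agrees with the tabulated value
        assert abs(gamma_from_yd(yd, 1.0, 0.5) - printed) <= 0.02

    def test_rejects_nonpositive(self):
        for args in [(-1, 1, 0.5), (2.3, 0, 0.5), (2.3, 1, 0)]:
            with pytest.raises(ValueError):
                gamma_from_yd(*args)


class TestRepairRate:
    def test_ln2_halftime_gives_unit_rate(self):
        assert repair_rate_from_halftime(math.log(2)) == pytest.approx(1.0, rel=1e-12)

    def test_one_hour_halftime(self):
        assert repair_rate_from_halftime(1.0) == pytest.approx(math.log(2), rel=1e-12)

    def test_study_repair_rate_roundtrip(self):
        # a+c = 0.46/h corresponds to a ~90 min repair half-time
        assert repair_rate_from_halftime(math.log(2) / 0.46) == pytest.approx(0.46, rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            repair_rate_from_halftime(0.0)


class TestSurvival:
    def test_zero_dose_survives(self, ff):
        pred = neg_log_survival(ff, DeliverySchedule(dose=0.0, duration=1.0))
        assert pred.neg_log_sf == 0.0
        assert pred.sf == 1.0

    def test_ff_2gy_1h(self, ff):
        # hand evaluation: alpha_eff = 0.24 + 2.96*0.06 = 0.4176,
        # F(0.46, 1 h) = 0.8628, -lnS = 0.4176*2 + 0.8628*0.06*4
        pred = neg_log_survival(ff, DeliverySchedule(dose=2.0, duration=1.0))
        assert pred.alpha_eff == pytest.approx(0.4176, rel=1e-12)
        assert pred.f_factor == pytest.approx(0.8628, abs=1e-4)
        assert pred.neg_log_sf == pytest.approx(1.0423, abs=2e-4)

    def test_fff_8gy_1h(self, fff):
        pred = neg_log_survival(fff, DeliverySchedule(dose=8.0, duration=1.0))
        assert pred.neg_log_sf == pytest.approx(7.214, abs=1e-3)

    def test_propagates_t_r_violation(self):
        params = MKMParameters(alpha0=0.24, beta0=0.06, repair_rate=0.46,
                               gamma=2.96, t_r=2.0)
        with pytest.raises(ValueError, match="t_r"):
            neg_log_survival(params, DeliverySchedule(dose=2.0, duration=3.0))


class TestInstantaneousDoseInversion:
    def test_zero_effect_zero_dose(self, ff):
        assert equivalent_instantaneous_dose(ff, 0.0) == 0.0

    def test_quadratic_root_value(self, ff):
        assert equivalent_instantaneous_dose(ff, 1.0423) == pytest.approx(1.950, abs=1e-3)

    def test_round_trip_is_identity(self, ff):
        for d in np.linspace(0.0, 20.0, 41):
            nls = neg_log_survival(ff, DeliverySchedule(dose=d, duration=0.0)).neg_log_sf
            assert equivalent_instantaneous_dose(ff, nls) == pytest.approx(d, rel=1e-10, abs=1e-12)

    def test_linear_special_case(self):
        params = MKMParameters(alpha0=0.3, beta0=0.0, repair_rate=0.46, gamma=2.96)
        assert equivalent_instantaneous_dose(params, 0.6) == pytest.approx(2.0, rel=1e-12)

    def test_rejects_negative_effect(self, ff):
        with pytest.raises(ValueError):
            equivalent_instantaneous_dose(ff, -0.1)


class TestRBE:
    def test_instantaneous_reference_is_unity(self, ff):
        for d in (0.5, 2.0, 8.0):
            assert rbe(ff, DeliverySchedule(dose=d, duration=0.0)).rbe == pytest.approx(1.0, rel=1e-12)

    def test_monotone_in_duration_and_dose(self, ff):
        grid_d = np.linspace(0.5, 10.0, 8)
        grid_t = np.linspace(0.0, 2.0, 9)
        table = np.array([
            [rbe(ff, DeliverySchedule(dose=d, duration=t)).rbe for t in grid_t]
            for d in grid_d
        ])
        assert np.all(table <= 1.0 + 1e-12)
        assert np.all(np.diff(table, axis=1) <= 1e-12)      # non-increasing in T
        assert np.all(table[1:, 1:] <= table[:-1, 1:] + 1e-12)  # non-increasing in D for T>0

    def test_pure_linear_cell_sees_no_protraction_effect(self):
        # with beta0 = 0 the protraction factor multiplies nothing
        params = MKMParameters(alpha0=0.3, beta0=0.0, repair_rate=0.46, gamma=2.96)
        assert rbe(params, DeliverySchedule(dose=4.0, duration=1.0)).rbe == pytest.approx(1.0, rel=1e-12)

    def test_undefined_at_zero_dose(self, ff):
        with pytest.raises(ValueError):
            rbe(ff, DeliverySchedule(dose=0.0, duration=1.0))


class TestParameters:
    def test_gamma_derived_from_yd(self):
        p = MKMParameters(alpha0=0.24, beta0=0.06, repair_rate=0.46, yd=2.32)
        assert p.gamma == pytest.approx(2.32 / (math.pi * 0.25), rel=1e-12)

    def test_inconsistent_gamma_and_yd_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MKMParameters(alpha0=0.24, beta0=0.06, repair_rate=0.46,
                          gamma=3.5, yd=2.32)

    def test_schedule_dose_rate(self):
        s = DeliverySchedule.from_minutes(2.0, 30.0)
        assert s.dose_rate * s.duration == pytest.approx(s.dose, rel=1e-12)
        with pytest.raises(ValueError):
            DeliverySchedule(dose=2.0, duration=0.0).dose_rate

    @pytest.mark.parametrize("bad", [
        dict(alpha0=-0.1, beta0=0.06, repair_rate=0.46, gamma=2.96),
        dict(alpha0=0.24, beta0=-0.1, repair_rate=0.46, gamma=2.96),
        dict(alpha0=0.24, beta0=0.06, repair_rate=0.0, gamma=2.96),
        dict(alpha0=0.24, beta0=0.06, repair_rate=0.46, gamma=-1.0),
        dict(alpha0=0.24, beta0=0.06, repair_rate=0.46),  # no gamma, no yd
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            MKMParameters(**bad)


class TestParameterFiles:
    def test_builtin_blocks(self, beams):
        assert set(beams) == {"FF", "FFF"}
        assert beams["FF"].alpha0 == 0.24
        assert beams["FFF"].beta0 == 0.07
        assert beams["FF"].repair_rate == 0.46

    def test_halftime_key_and_missing_key(self, tmp_path):
        good = tmp_path / "good.toml"
        good.write_text(
            "[beam.X]\nalpha0 = 0.2\nbeta0 = 0.05\n"
            f"repair_halftime_h = {math.log(2) / 0.46}\nyd_kev_um = 2.32\n"
        )
        blocks = load_parameter_blocks(good)
        assert blocks["X"].repair_rate == pytest.approx(0.46, rel=1e-12)

        bad = tmp_path / "bad.toml"
        bad.write_text("[beam.Y]\nalpha0 = 0.2\nrepair_rate_per_h = 0.46\ngamma = 2.9\n")
        with pytest.raises(ValueError, match="'Y'.*beta0"):
            load_parameter_blocks(bad)
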