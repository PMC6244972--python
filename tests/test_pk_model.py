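"""Structural PK model: simulation, linear-limit oracles, allometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkpdkit.pk_model import (
    AllometricRule,
    DoseEvent,
    PKParameters,
    Regimen,
    human_default_params,
    mouse_default_params,
    scale_params,
    simulate,
)

from conftest import biexponential_bolus


class TestSimulate:
    def test_zero_dose_gives_zero_concentration(self, human_params):
        regimen = Regimen((DoseEvent(0.0, 0.0),))
        course = simulate(human_params, regimen, np.linspace(0, 504, 30))
        assert np.all(course.concentrations == 0.0)

    def test_bolus_initial_concentration_is_dose_over_v1(self, human_params):
        course = simulate(human_params, Regimen.single_dose(360.0), np.array([0.0]))
        assert course.concentrations[0] == pytest.approx(360.0 / 3.17, rel=1e-12)

    def test_linear_limit_matches_biexponential_closed_form(self, human_params):
        params = human_params.replace(Vmax=1e-30)  # effectively linear
        times = np.linspace(0.0, 1000.0, 80)
        course = simulate(params, Regimen.single_dose(360.0), times,
                          rtol=1e-10, atol=1e-12)
        expected = biexponential_bolus(params, 360.0, times)
        np.testing.assert_allclose(course.concentrations, expected, rtol=1e-6)

    @settings(max_examples=15, deadline=None)
    @given(
        cl=st.floats(1e-3, 1.0), v1=st.floats(0.5, 50.0),
        q=st.floats(1e-3, 1.0), v2=st.floats(0.5, 50.0),
    )
    def test_linear_oracle_over_parameter_space(self, cl, v1, q, v2):
        """Bi-exponential closed form holds across three orders of magnitude."""
        params = PKParameters(CL=cl, V1=v1, Q=q, V2=v2, Vmax=1e-30, Km=0.219)
        times = np.linspace(0.0, 300.0, 40)
        course = simulate(params, Regimen.single_dose(100.0), times,
                          rtol=1e-10, atol=1e-12)
        expected = biexponential_bolus(params, 100.0, times)
        # atol covers concentrations that have decayed to numerical zero
        np.testing.assert_allclose(course.concentrations, expected, rtol=1e-6,
                                   atol=1e-9)

    def test_mass_balance_without_elimination(self, human_params):
        params = human_params.replace(CL=0.0, Vmax=0.0)
        regimen = Regimen((DoseEvent(0.0, 100.0), DoseEvent(100.0, 50.0),
                           DoseEvent(250.0, 25.0)))
        course = simulate(params, regimen, np.linspace(0, 500, 60))
        total = course.amounts.sum(axis=1)
        dosed = np.where(course.times >= 250, 175.0,
                         np.where(course.times >= 100, 150.0, 100.0))
        np.testing.assert_allclose(total, dosed, rtol=1e-7)

    def test_superposition_holds_iff_linear(self, human_params):
        times = np.linspace(0.0, 1008.0, 60)
        single = Regimen.single_dose(100.0)
        double = Regimen((DoseEvent(0.0, 100.0), DoseEvent(504.0, 100.0)))
        shifted = Regimen((DoseEvent(504.0, 100.0),))

        linear = human_params.replace(Vmax=1e-30)
        sum_of_singles = (
            simulate(linear, single, times).concentrations
            + simulate(linear, shifted, times).concentrations
        )
        multi = simulate(linear, double, times).concentrations
        np.testing.assert_allclose(multi, sum_of_singles, rtol=1e-6, atol=1e-12)

        # saturable clearance breaks superposition near Km: dose again while
        # the first dose's concentration still sits in the half-saturation
        # region
        short = np.linspace(0.0, 48.0, 60)
        sum_small = (
            simulate(human_params, Regimen.single_dose(2.0), short).concentrations
            + simulate(human_params, Regimen((DoseEvent(4.0, 2.0),)), short).concentrations
        )
        multi_small = simulate(
            human_params, Regimen((DoseEvent(0.0, 2.0), DoseEvent(4.0, 2.0))), short
        ).concentrations
        late = short > 4.0
        assert np.max(np.abs(multi_small[late] - sum_small[late])
                      / np.maximum(sum_small[late], 1e-12)) > 1e-3

    def test_dose_event_time_reports_post_dose_state(self, human_params):
        regimen = Regimen((DoseEvent(0.0, 100.0), DoseEvent(168.0, 100.0)))
        course = simulate(human_params, regimen, np.array([0.0, 167.999, 168.0]))
        jump = course.concentrations[2] - course.concentrations[1]
        assert jump == pytest.approx(100.0 / human_params.V1, rel=1e-3)

    def test_unsorted_times_rejected(self, human_params):
        with pytest.raises(ValueError):
            simulate(human_params, Regimen.single_dose(10.0), np.array([5.0, 1.0]))


class TestMonotoneSaturation:
    def test_auc_per_dose_nondecreasing_in_dose(self, human_params):
        from pkpdkit.exposure import auc_inf

        doses = [1.0, 10.0, 100.0, 500.0, 1000.0, 2000.0]
        ratios = [auc_inf(human_params, d) / d for d in doses]
        assert all(r2 >= r1 * (1 - 1e-9) for r1, r2 in zip(ratios, ratios[1:]))


class TestAllometry:
    def test_published_mouse_column_reproduced(self, human_params):
        """Scaling the 70 kg anchor to 0.02 kg reproduces the published
        mouse parameter set at printed precision."""
        mouse = scale_params(human_params, AllometricRule(), 0.02)
        assert mouse.CL == pytest.approx(2.75e-5, rel=2e-3)
        assert mouse.V1 == pytest.approx(9.06e-4, rel=2e-3)
        assert mouse.Q == pytest.approx(6.88e-5, rel=2e-3)
        assert mouse.V2 == pytest.approx(1.00e-3, rel=5e-3)
        assert mouse.Vmax == pytest.approx(1.10e-3, rel=2e-3)
        assert mouse.Km == 0.219  # not scaled: drug-target property

    def test_identity_scaling(self, human_params):
        same = scale_params(human_params, AllometricRule(), 70.0)
        assert same == human_params

    def test_round_trip_recovers_anchor(self, human_params):
        rule = AllometricRule()
        mouse = scale_params(human_params, rule, 0.02)
        back = scale_params(mouse, AllometricRule(reference_weight=0.02), 70.0)
        for name in ("CL", "V1", "Q", "V2", "Vmax", "Km"):
            assert getattr(back, name) == pytest.approx(getattr(human_params, name),
                                                        rel=1e-12)

    def test_nonpositive_weight_rejected(self, human_params):
        with pytest.raises(ValueError):
            scale_params(human_params, AllometricRule(), 0.0)

    def test_km_scaling_opt_in(self, human_params):
        scaled = scale_params(human_params, AllometricRule(scale_km=True), 0.02)
        assert scaled.Km < human_params.Km


class TestDefaults:
    def test_published_typical_values(self):
        h = human_default_params()
        assert (h.CL, h.V1, h.Q, h.V2, h.Vmax, h.Km) == (
            0.0125, 3.17, 0.0313, 3.51, 0.500, 0.219)

    def test_mouse_defaults_are_scaled_anchor(self):
        m = mouse_default_params()
        expected = scale_params(human_default_params(), AllometricRule(), 0.02)
        assert m == expected


class TestValidation:
    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            PKParameters(CL=0.01, V1=-1.0, Q=0.03, V2=3.5, Vmax=0.5, Km=0.2)

    def test_events_must_be_sorted(self):
        with pytest.raises(ValueError):
            Regimen((DoseEvent(100.0, 1.0), DoseEvent(0.0, 1.0)))

    def test_unknown_route_rejected(self):
        with pytest.raises(ValueError):
            DoseEvent(0.0, 1.0, route="oral")
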