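"""Base-case parameter values, validation, config round-trips, SA bounds."""
import numpy as np
import pytest

import dtxecon as dx
from dtxecon.parameters import (
    CALIBRATED,
    ParameterError,
    parameters_equal,
    registry_frame,
    sa_registry,
)


class TestDefaults:
    @pytest.mark.parametrize("disease, getter, expected", [
        ("t2dm", lambda p: p.med_costs["t2dm"].base_annual_cost, 2466.0),
        ("t2dm", lambda p: p.med_costs["hc"].base_annual_cost, 775.0),
        ("t2dm", lambda p: p.med_costs["htn"].base_annual_cost, 1557.0),
        ("t2dm", lambda p: p.med_costs["t2dm"].slopes, (0.0, 0.33, 1.2, 2.2)),
        ("t2dm", lambda p: p.med_costs["hc"].slopes, (0.5, 0.8, 1.5, 2.0)),
        ("t2dm", lambda p: p.cvd_hazard_ratios, (1.0, 1.0, 1.25, 1.98)),
        ("t2dm", lambda p: p.cvd_event_cost, 116423.0),
        ("t2dm", lambda p: p.comorbidity_prevalence, {"hc": 0.60, "htn": 0.60}),
        ("t2dm", lambda p: p.utilities.anchor_utility, 0.82),
        ("t2dm", lambda p: p.synthesis.responder_fraction_y1, 0.62),
        ("t2dm", lambda p: p.synthesis.mean_change_y1, -0.8),
        ("t2dm", lambda p: p.discount_rate, 0.03),
        ("htn", lambda p: p.med_costs["htn"].slopes, (0.0, 0.15, 0.9, 1.8)),
        ("htn", lambda p: p.comorbidity_prevalence, {"t2dm": 0.33}),
        ("htn", lambda p: p.utilities.anchor_utility, 0.83),
        ("htn", lambda p: p.utilities.cat4_increment, 0.0),
        ("htn", lambda p: p.synthesis.responder_fraction_y1, 0.87),
        ("htn", lambda p: p.synthesis.mean_change_y1, -11.0),
        ("htn", lambda p: p.cat2_unmedicated_fraction, 0.25),
    ])
    def test_printed_values(self, disease, getter, expected):
        assert getter(dx.default_parameters(disease)) == expected

    def test_enrollment_distributions(self):
        np.testing.assert_allclose(
            dx.default_parameters("t2dm").enrollment_distribution, [0, 0.47, 0.34, 0.19])
        np.testing.assert_allclose(
            dx.default_parameters("htn").enrollment_distribution, [0, 0.37, 0.19, 0.44])

    def test_delays_and_attrition(self, params):
        assert params.delays.medication_delay_months == 6.0
        assert params.delays.cvd_delay_months == 3.0
        a = params.attrition
        assert (a.y1_early, a.y1_late, a.y2, a.y3) == (0.20, 0.20, 0.10, 0.10)

    def test_defaults_pass_their_own_validation(self, params):
        params.validate()

    def test_category_bounds(self):
        assert dx.T2DM.category_bounds == (6.5, 7.5, 9.0)
        assert dx.HTN.category_bounds == (120.0, 130.0, 140.0)

    def test_unknown_disease_rejected(self):
        with pytest.raises(ParameterError, match="unknown disease"):
            dx.default_parameters("copd")

    def test_calibrated_placeholders_are_documented_inputs(self):
        # the unprinted quantities ship as explicit named constants
        assert set(CALIBRATED) == {"t2dm", "htn"}
        assert dx.default_parameters("t2dm").baseline_cvd_annual_rate == \
            CALIBRATED["t2dm"]["baseline_cvd_annual_rate"]


class TestUtilities:
    def test_anchor_and_increments(self, t2dm):
        u = t2dm.utilities
        assert u.utility(2, on_medications=False) == 0.82
        assert u.utility(2, on_medications=True) == pytest.approx(0.80)
        assert u.utility(1) == pytest.approx(0.84)

    def test_cvd_event_decrement(self, params):
        u = params.utilities
        for cat in (1, 2, 3, 4):
            assert u.utility(cat, cvd_event=True) == pytest.approx(
                u.utility(cat) - 0.1)

    def test_cumulative_mode_is_monotone(self, t2dm):
        t2dm.utilities.increment_mode = "cumulative"
        vals = [t2dm.utilities.utility(c) for c in (1, 2, 3, 4)]
        assert vals == sorted(vals, reverse=True)

    def test_clamped_to_unit_interval(self):
        u = dx.UtilitySet(anchor_utility=0.05, cat1_increment=0.02,
                          cat2_on_meds_increment=-0.02, cat3_increment=-0.035,
                          cat4_increment=-0.025)
        assert u.utility(4, cvd_event=True) == 0.0


class TestConfigIO:
    def test_round_trip_is_lossless(self, params):
        text = dx.serialize_parameters(params)
        assert parameters_equal(dx.load_parameters(text), params)

    def test_round_trip_with_tables(self, htn):
        htn.transition_tables = dx.synthesize_transition_tables(htn)
        reloaded = dx.load_parameters(dx.serialize_parameters(htn))
        np.testing.assert_allclose(reloaded.transition_tables.year1,
                                   htn.transition_tables.year1)

    def test_single_override_keeps_base(self, disease):
        p = dx.load_parameters({"disease": disease, "discount_rate": 0.0})
        assert p.discount_rate == 0.0
        base = dx.default_parameters(disease)
        base.discount_rate = 0.0
        assert parameters_equal(p, base)

    def test_invalid_enrollment_named_in_error(self):
        cfg = {"disease": "t2dm", "enrollment_distribution": [0, 0.4, 0.3, 0.2]}
        with pytest.raises(ParameterError, match="enrollment_distribution"):
            dx.load_parameters(cfg)

    def test_unknown_key_rejected(self):
        with pytest.raises(ParameterError, match="unknown config key"):
            dx.load_parameters({"disease": "htn", "discout_rate": 0.0})

    def test_non_stochastic_table_rejected(self, t2dm):
        t2dm.transition_tables = dx.synthesize_transition_tables(t2dm)
        cfg = t2dm.to_config()
        cfg["transition_tables"]["year1"][1][0] += 0.05
        with pytest.raises(ParameterError, match="not stochastic"):
            dx.load_parameters(cfg)


class TestSABounds:
    def test_mean_improvement_asymmetric(self, t2dm):
        low = dx.apply_sa_bound(t2dm, "dtx_mean_improvement", "low")
        high = dx.apply_sa_bound(t2dm, "dtx_mean_improvement", "high")
        assert low.synthesis.mean_change_y1 == pytest.approx(-0.48)
        assert high.synthesis.mean_change_y1 == pytest.approx(-0.96)
        assert low.transition_tables is None   # forces re-synthesis

    def test_discount_rate_bounds(self, params):
        assert dx.apply_sa_bound(params, "discount_rate", "high").discount_rate == 0.05
        assert dx.apply_sa_bound(params, "discount_rate", "low").discount_rate == 0.0

    def test_cat2_unmedicated_bounds(self, htn):
        assert dx.apply_sa_bound(htn, "cat2_unmedicated_fraction", "low") \
            .cat2_unmedicated_fraction == 0.0
        assert dx.apply_sa_bound(htn, "cat2_unmedicated_fraction", "high") \
            .cat2_unmedicated_fraction == 0.50

    def test_gradient_scaling_moves_all_slopes(self, t2dm):
        high = dx.apply_sa_bound(t2dm, "t2dm_med_gradient", "high")
        np.testing.assert_allclose(
            high.med_costs["t2dm"].slopes,
            np.asarray(t2dm.med_costs["t2dm"].slopes) * 1.1)

    def test_symmetric_ranges_are_equidistant(self, params):
        for entry in sa_registry(params):
            if entry.kind == "relative" and entry.high == -entry.low:
                base = entry.getter(params)
                lo = entry.bound_value(params, "low")
                hi = entry.bound_value(params, "high")
                assert hi - base == pytest.approx(base - lo)

    def test_input_object_unmodified(self, t2dm):
        snapshot = t2dm.to_config()
        dx.apply_sa_bound(t2dm, "cvd_event_cost", "high")
        assert t2dm.to_config() == snapshot

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(ParameterError, match="no sensitivity range"):
            dx.apply_sa_bound(params, "not_a_parameter", "low")

    def test_registry_export_columns(self, params):
        df = registry_frame(params)
        assert list(df.columns) == ["name", "base_value", "sa_low", "sa_high",
                                    "units", "printed_form"]
        assert len(df) > 10 and df["name"].is_unique
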