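"""Medication and CVD cost arithmetic, delays, discounting, and arm-level
cost properties."""
import numpy as np
import pytest

import dtxecon as dx
from dtxecon.costs import cvd_rate_vector, savings_by_year

from conftest import make_null_effect


class TestMedicationCost:
    def test_zero_slope_costs_nothing(self, t2dm):
        assert dx.medication_cost(1, t2dm.med_costs["t2dm"]) == 0.0

    def test_category4_product(self, t2dm):
        assert dx.medication_cost(4, t2dm.med_costs["t2dm"]) == pytest.approx(5425.20)

    def test_category2_unmedicated_discount(self, t2dm):
        assert dx.medication_cost(2, t2dm.med_costs["t2dm"], 0.25) == \
            pytest.approx(2466 * 0.33 * 0.75)
        # the discount applies to category 2 only
        assert dx.medication_cost(3, t2dm.med_costs["t2dm"], 0.25) == \
            pytest.approx(2466 * 1.2)

    def test_invalid_category(self, t2dm):
        with pytest.raises(dx.ParameterError):
            dx.medication_cost(5, t2dm.med_costs["t2dm"])


class TestComorbidCost:
    def test_t2dm_model_category3(self, t2dm):
        expected = 0.60 * 775 * 1.5 + 0.60 * 1557 * 0.9
        assert dx.comorbid_med_cost(3, t2dm.comorbidity_prevalence,
                                    t2dm.med_costs) == pytest.approx(expected)

    def test_htn_model_category2_uses_t2dm_gradient(self, htn):
        assert dx.comorbid_med_cost(2, htn.comorbidity_prevalence,
                                    htn.med_costs) == pytest.approx(0.33 * 2466 * 0.33)

    def test_zero_prevalence_costs_nothing(self, t2dm):
        assert dx.comorbid_med_cost(4, {"hc": 0.0, "htn": 0.0}, t2dm.med_costs) == 0.0


class TestCvdRates:
    def test_hazard_ratio_arithmetic(self):
        hrs = (1.0, 1.0, 1.25, 1.98)
        assert dx.cvd_annual_rate_t2dm(1, 0.02, hrs) == dx.cvd_annual_rate_t2dm(2, 0.02, hrs)
        assert dx.cvd_annual_rate_t2dm(4, 0.02, hrs) == pytest.approx(0.02 * 1.98)
        assert dx.cvd_annual_rate_t2dm(3, 0.0, hrs) == 0.0

    def test_framingham_rates_increase_with_category(self, htn):
        rates = cvd_rate_vector(htn, dtx_active=False)
        assert (np.diff(rates) > 0).all()

    def test_rates_scale_with_calibrated_factor(self, htn):
        base = cvd_rate_vector(htn, dtx_active=False)
        htn.cvd_rate_scale *= 2.0
        np.testing.assert_allclose(cvd_rate_vector(htn, dtx_active=False), 2 * base)


class TestDelayAndDiscount:
    @pytest.mark.parametrize("saving, delay, year, expected", [
        (1000.0, 12.0, 1, 0.0),
        (1000.0, 6.0, 1, 500.0),
        (1000.0, 6.0, 2, 1000.0),
        (1000.0, 0.0, 1, 1000.0),
    ])
    def test_benefit_delay_proration(self, saving, delay, year, expected):
        assert dx.apply_benefit_delay(saving, delay, year) == expected

    def test_discount_closed_forms(self):
        assert dx.discount(100.0, 3, 0.0) == 100.0
        assert dx.discount(100.0, 1, 0.03) == 100.0
        assert dx.discount(100.0, 3, 0.03) == pytest.approx(100 / 1.03 ** 2)


class TestArmCosts:
    def test_null_effect_breakdowns_identical(self, disease):
        p = make_null_effect(disease)
        costs = {arm: dx.arm_costs(dx.simulate_cohort(p, arm), p)
                 for arm in ("TAU", "DTX_TAU")}
        for comp in ("disease_med", "comorbid_med", "cvd_inpatient"):
            np.testing.assert_allclose(costs["TAU"].undiscounted[comp],
                                       costs["DTX_TAU"].undiscounted[comp])

    def test_cvd_cost_linear_in_event_cost(self, t2dm):
        run1 = dx.run_model(t2dm.copy())
        doubled = t2dm.copy(cvd_event_cost=t2dm.cvd_event_cost * 2)
        run2 = dx.run_model(doubled)
        for arm in ("TAU", "DTX_TAU"):
            np.testing.assert_allclose(
                run2.costs[arm].undiscounted["cvd_inpatient"],
                2 * run1.costs[arm].undiscounted["cvd_inpatient"])
            np.testing.assert_allclose(
                run2.costs[arm].undiscounted["disease_med"],
                run1.costs[arm].undiscounted["disease_med"])

    def test_flat_gradients_and_unit_hrs_zero_incremental(self, t2dm):
        t2dm.med_costs["t2dm"] = dx.CostGradient(2466.0, (1.0, 1.0, 1.0, 1.0))
        t2dm.med_costs["hc"] = dx.CostGradient(775.0, (1.0, 1.0, 1.0, 1.0))
        t2dm.med_costs["htn"] = dx.CostGradient(1557.0, (1.0, 1.0, 1.0, 1.0))
        t2dm.cvd_hazard_ratios = (1.0, 1.0, 1.0, 1.0)
        t2dm.cat2_unmedicated_fraction = 0.0
        run = dx.run_model(t2dm)
        np.testing.assert_allclose(run.savings(), np.zeros(3), atol=1e-9)

    def test_savings_nondecreasing_in_med_base_cost(self, params):
        run_lo = dx.run_model(params.copy())
        hi = params.copy()
        hi.med_costs[params.disease.key].base_annual_cost *= 1.5
        run_hi = dx.run_model(hi)
        assert (run_hi.savings() >= run_lo.savings() - 1e-9).all()

    def test_savings_monotone_in_medication_delay(self, params):
        runs = {}
        for d in (3.0, 6.0, 9.0):
            p = params.copy()
            p.delays.medication_delay_months = d
            runs[d] = dx.run_model(p)
        assert runs[3.0].pppm[0] > runs[6.0].pppm[0] > runs[9.0].pppm[0]
        # years 2-3 are delay-invariant
        for y in (2, 3):
            assert runs[3.0].pppm[y - 1] == pytest.approx(runs[9.0].pppm[y - 1])

    def test_discount_rate_ordering_of_total_savings(self, params):
        totals = {}
        for rate in (0.0, 0.03, 0.05):
            p = params.copy(discount_rate=rate)
            run = dx.run_model(p)
            totals[rate] = run.savings(discounted=True).sum()
        assert totals[0.0] >= totals[0.03] >= totals[0.05]
        assert totals[0.0] > totals[0.05]

    def test_pppm_denominator_conventions(self, base_runs, disease):
        run = base_runs[disease]
        enrolled = dx.pppm_savings(run.costs["TAU"], run.costs["DTX_TAU"], 2,
                                   "enrolled_months")
        active = dx.pppm_savings(run.costs["TAU"], run.costs["DTX_TAU"], 2,
                                 "active_months")
        # fewer active person-months than enrolled months -> larger PPPM
        assert active > enrolled

    def test_breakdown_frame_shape(self, base_runs, disease):
        df = base_runs[disease].costs["TAU"].to_frame()
        assert set(df["component"]) == {"disease_med", "comorbid_med", "cvd_inpatient"}
        assert len(df) == 9
        assert (df["discounted"] <= df["undiscounted"] + 1e-12).all()
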