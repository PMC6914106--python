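"""Health-resource costs: category-gradient medications, comorbidity
medications, and CVD inpatient events, with clinical-inertia delay gating and
discounting.

The T2DM model prices CVD events as a calibrated baseline annual rate scaled
by printed hazard ratios per HbA1c category; the HTN model derives per-category
rates from the Framingham general-CVD equation at each category's
representative SBP (mixed over sex, smoking, and comorbid diabetes), converted
to annual probabilities and multiplied by a calibrated payer scale.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTrajectory, Segment
from .framingham import FraminghamProfile, framingham_10yr_risk, tenyr_to_annual
from .parameters import CostGradient, ModelParameters, ParameterError

COMPONENTS = ("disease_med", "comorbid_med", "cvd_inpatient")


def medication_cost(category: int, gradient: CostGradient,
                    unmedicated_fraction: float = 0.0) -> float:
    """Expected annual primary-disease medication cost for one category.

    ``unmedicated_fraction`` is the share of category-2 patients managed by
    the DTx alone, without pharmacologic treatment; it discounts category 2
    only (pass 0 for the TAU arm).
    """
    if category not in (1, 2, 3, 4):
        raise ParameterError(f"category must be 1-4, got {category}")
    cost = gradient.annual_cost(category)
    if category == 2:
        cost *= (1.0 - unmedicated_fraction)
    return cost


def comorbid_med_cost(category: int, comorbidity_prevalence: dict[str, float],
                      gradients: dict[str, CostGradient]) -> float:
    """Prevalence-weighted comorbidity medication cost; the primary-disease
    category indexes every comorbidity gradient (an improvement in the
    primary biomarker lowers comorbid medication intensity in step)."""
    if category not in (1, 2, 3, 4):
        raise ParameterError(f"category must be 1-4, got {category}")
    return float(sum(prev * gradients[name].annual_cost(category)
                     for name, prev in comorbidity_prevalence.items()))


def cvd_annual_rate_t2dm(category: int, baseline_rate: float,
                         hazard_ratios) -> float:
    """Annual CVD event rate: baseline times the category's hazard ratio."""
    if baseline_rate < 0:
        raise ParameterError("baseline_rate must be >= 0")
    return baseline_rate * float(hazard_ratios[category - 1])


def apply_benefit_delay(undelayed_annual_saving: float, delay_months: float,
                        year: int) -> float:
    """Clinical-inertia proration: a year-1 saving accrues only over the
    months after the delay elapses; later years are unaffected."""
    if not (0.0 <= delay_months <= 12.0):
        raise ParameterError(f"delay_months must be in [0, 12], got {delay_months}")
    if year == 1:
        return undelayed_annual_saving * (12.0 - delay_months) / 12.0
    return undelayed_annual_saving


def discount(value: float, year: int, rate: float):
    """Present value with year 1 undiscounted: value / (1+rate)**(year-1)."""
    if rate < 0:
        raise ParameterError("discount rate must be >= 0")
    return value / (1.0 + rate) ** (year - 1)


# ---------------------------------------------------------------------------
# Per-category vectors
# ---------------------------------------------------------------------------

def disease_med_vector(params: ModelParameters, dtx_active: bool) -> np.ndarray:
    g = params.med_costs[params.disease.key]
    uf = params.cat2_unmedicated_fraction if dtx_active else 0.0
    return np.array([medication_cost(c, g, uf) for c in (1, 2, 3, 4)])


def comorbid_med_vector(params: ModelParameters) -> np.ndarray:
    return np.array([comorbid_med_cost(c, params.comorbidity_prevalence, params.med_costs)
                     for c in (1, 2, 3, 4)])


def treated_fraction_by_category(params: ModelParameters, dtx_active: bool) -> np.ndarray:
    """Share of each category on antihypertensive treatment (HTN model):
    categories with medication slope 0 are untreated; in the DTx arm the
    category-2 unmedicated share is off treatment."""
    slopes = np.asarray(params.med_costs[params.disease.key].slopes, dtype=float)
    treated = (slopes > 0).astype(float)
    if dtx_active:
        treated[1] *= (1.0 - params.cat2_unmedicated_fraction)
    return treated


def cvd_rate_vector(params: ModelParameters, dtx_active: bool) -> np.ndarray:
    """Annual CVD event rate per category for one arm/status."""
    if params.cvd_hazard_ratios is not None:
        hrs = np.asarray(params.cvd_hazard_ratios, dtype=float)
        return params.cvd_rate_scale * params.baseline_cvd_annual_rate * hrs

    fa = params.framingham
    reps = params.disease.representative_values
    treated = treated_fraction_by_category(params, dtx_active)
    dm_prev = params.diabetic_prevalence
    rates = np.zeros(4)
    for c in range(4):
        r = 0.0
        for sex, psex in (("F", fa.female_fraction), ("M", 1.0 - fa.female_fraction)):
            for smoker, psm in ((True, fa.smoking_prevalence), (False, 1.0 - fa.smoking_prevalence)):
                for diabetic, pdm in ((True, dm_prev), (False, 1.0 - dm_prev)):
                    for rx, prx in ((True, treated[c]), (False, 1.0 - treated[c])):
                        w = psex * psm * pdm * prx
                        if w == 0.0:
                            continue
                        p10 = framingham_10yr_risk(FraminghamProfile(
                            age=params.mean_age, sex=sex, systolic_bp=reps[c],
                            bp_treated=rx, smoker=smoker, diabetic=diabetic,
                            total_cholesterol=fa.total_cholesterol,
                            hdl_cholesterol=fa.hdl_cholesterol))
                        r += w * tenyr_to_annual(p10)
        rates[c] = r
    return params.cvd_rate_scale * rates


# ---------------------------------------------------------------------------
# Arm-level costs
# ---------------------------------------------------------------------------

@dataclass
class AnnualCostBreakdown:
    """Per-arm, per-year cost components in USD per original enrollee.

    ``undiscounted[component]`` are nominal ("year 1 dollar") arrays over
    years 1..3; ``discounted`` applies the model's rate with year 1 as the
    present.  ``person_months`` holds both PPPM denominator conventions.
    """

    arm: str
    undiscounted: dict[str, np.ndarray]
    discounted: dict[str, np.ndarray]
    person_months: dict[str, np.ndarray]

    def total(self, discounted: bool = False) -> np.ndarray:
        table = self.discounted if discounted else self.undiscounted
        return sum(table[c] for c in COMPONENTS)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in COMPONENTS:
            for i, year in enumerate((1, 2, 3)):
                rows.append({"arm": self.arm, "year": year, "component": comp,
                             "undiscounted": self.undiscounted[comp][i],
                             "discounted": self.discounted[comp][i]})
        return pd.DataFrame(rows)


def _segment_costs(seg: Segment, params: ModelParameters,
                   vectors: dict) -> tuple[float, float, float]:
    """(disease_med, comorbid_med, cvd_inpatient) annual-rate costs of one
    segment, per unit mass, before mass/part-year weighting."""
    status = "dtx" if seg.dtx_active else "tau"
    med_v, com_v, cvd_v = vectors[status]
    if seg.delayed_from is None:
        d = seg.distribution
        return float(d @ med_v), float(d @ com_v), float((d @ cvd_v) * params.cvd_event_cost)
    # year-1 clinical inertia: pre-delay months at the pre-improvement
    # (enrollment) distribution under TAU medication status
    med_tau, com_tau, cvd_tau = vectors["tau"]
    fm = params.delays.medication_delay_months / 12.0
    fc = params.delays.cvd_delay_months / 12.0
    pre, post = seg.delayed_from, seg.distribution
    med = fm * (pre @ med_tau) + (1.0 - fm) * (post @ med_v)
    com = fm * (pre @ com_tau) + (1.0 - fm) * (post @ com_v)
    cvd = (fc * (pre @ cvd_tau) + (1.0 - fc) * (post @ cvd_v)) * params.cvd_event_cost
    return float(med), float(com), float(cvd)


def arm_costs(trajectory: CohortTrajectory, params: ModelParameters) -> AnnualCostBreakdown:
    """Discounted annual cost components for one arm, per original enrollee,
    costing each trajectory segment at its category distribution and status."""
    com_v = comorbid_med_vector(params)
    vectors = {
        "dtx": (disease_med_vector(params, True), com_v, cvd_rate_vector(params, True)),
        "tau": (disease_med_vector(params, False), com_v, cvd_rate_vector(params, False)),
    }
    und = {c: np.zeros(3) for c in COMPONENTS}
    pm = {"enrolled_months": np.full(3, 12.0), "active_months": np.zeros(3)}
    for y in (1, 2, 3):
        st = trajectory.years[y]
        for seg in st.segments:
            w = seg.mass * seg.year_fraction
            med, com, cvd = _segment_costs(seg, params, vectors)
            und["disease_med"][y - 1] += w * med
            und["comorbid_med"][y - 1] += w * com
            und["cvd_inpatient"][y - 1] += w * cvd
            if seg.dtx_active:
                pm["active_months"][y - 1] += w * 12.0
    if trajectory.arm == "TAU":
        pm["active_months"] = np.full(3, 12.0)
    years = np.arange(1, 4)
    disc = {c: discount(und[c], years, params.discount_rate) for c in COMPONENTS}
    return AnnualCostBreakdown(arm=trajectory.arm, undiscounted=und, discounted=disc,
                               person_months=pm)


def pppm_savings(tau: AnnualCostBreakdown, dtx: AnnualCostBreakdown, year: int,
                 denominator: str = "enrolled_months") -> float:
    """Per-participant-per-month HRU savings for one year, in nominal
    ("year 1") dollars: (TAU total - DTx total) / person-months.

    The default denominator counts all original enrollees (12 months each);
    ``'active_months'`` divides by DTx program person-months instead.
    """
    i = year - 1
    months = dtx.person_months[denominator][i]
    if months == 0:
        raise ZeroDivisionError(f"zero person-months in year {year}")
    return float((tau.total()[i] - dtx.total()[i]) / months)


def savings_by_year(tau: AnnualCostBreakdown, dtx: AnnualCostBreakdown,
                    discounted: bool = False) -> np.ndarray:
    return tau.total(discounted) - dtx.total(discounted)
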