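"""Synthetic inputs: transition tables honoring the printed year-1
effectiveness constraints, randomized parameter sets for property tests, and
an individual-level microsimulation serving as brute-force oracle for the
deterministic cohort engine.

Table synthesis ansatz
----------------------
Year 1: a fraction r of patients in each enrolled category (the responder
fraction) improves at least one category; non-responders persist.  One scalar
degree of freedom theta tunes the implied mean biomarker change (category
midpoints as representative values) to the printed target:

* theta < 0: a fraction ``-theta`` of non-responders worsens one category
  (weaker mean change than single-category moves imply);
* theta in (0, 1]: a fraction ``theta`` of category-3/4 responders jumps two
  categories;
* theta in (1, 2]: additionally a fraction ``theta - 1`` of category-4
  responders jumps three categories.

The implied mean change is monotone in theta, so a root exists iff the target
lies in the achievable interval; otherwise synthesis fails loudly with the
achievable range (never a silent approximation).

Years 2-3: each active patient improves one category with the year's
incremental-improvement probability, damped for the enrolled-category-4
stratum ("more resistant to improvements"); everyone else persists.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from . import cohort as _cohort
from .parameters import (
    ModelParameters,
    SynthesisConstraints,
    TransitionTable,
    default_parameters,
    sa_registry,
)

MEAN_TOL = 1e-6
RESPONDER_TOL = 1e-9


class InfeasibleConstraints(ValueError):
    """The synthesis constraints cannot be met from the enrollment
    distribution and category representative values."""


def _year1_matrix(theta: float, r: float) -> np.ndarray:
    f2 = min(max(theta, 0.0), 1.0)
    f3 = max(theta - 1.0, 0.0)
    w = max(-theta, 0.0)
    M = np.zeros((4, 4))
    M[0, 0] = 1.0
    # category 2: responders can only reach category 1
    M[1, 0] = r
    M[1, 1] = (1 - r) * (1 - w)
    M[1, 2] = (1 - r) * w
    # category 3: two-category jump also ends at category 1
    M[2, 0] = r * f2
    M[2, 1] = r * (1 - f2)
    M[2, 2] = (1 - r) * (1 - w)
    M[2, 3] = (1 - r) * w
    # category 4: worsening reflects (stays); deepest jump reaches category 1
    M[3, 0] = r * f3
    M[3, 1] = r * (f2 - f3)
    M[3, 2] = r * (1 - f2)
    M[3, 3] = 1 - r
    return M


def _later_matrix(improvement: float, damping: float) -> np.ndarray:
    """(enrollment, from, to) operator for one of years 2-3."""
    M = np.zeros((4, 4, 4))
    for c in range(4):
        i = improvement * (damping if c == 3 else 1.0)
        M[c, 0, 0] = 1.0
        for j in (1, 2, 3):
            M[c, j, j - 1] = i
            M[c, j, j] = 1.0 - i
    return M


def achievable_mean_range(params: ModelParameters,
                          constraints: SynthesisConstraints | None = None
                          ) -> tuple[float, float]:
    """(strongest, weakest) year-1 mean biomarker change reachable by the
    table ansatz given the enrollment distribution and responder fraction."""
    con = constraints or params.synthesis
    e = np.asarray(params.enrollment_distribution, dtype=float)
    reps = params.disease.representative_values
    improvable = 1.0 - e[0]
    r = 0.0 if improvable == 0 else min(con.responder_fraction_y1 / improvable, 1.0)

    def mean_change(theta: float) -> float:
        out = e @ _year1_matrix(theta, r)
        return float((out - e) @ reps)

    return mean_change(2.0), mean_change(-1.0)


def synthesize_transition_tables(params: ModelParameters,
                                 constraints: SynthesisConstraints | None = None,
                                 seed: int | None = None) -> TransitionTable:
    """Row-stochastic 3-year tables whose implied year-1 responder fraction
    equals the constraint exactly and whose implied mean biomarker change
    matches within ``MEAN_TOL``.  Deterministic (the ansatz has a unique
    solution; ``seed`` is accepted for interface uniformity and unused)."""
    con = constraints or params.synthesis
    con.validate()
    e = np.asarray(params.enrollment_distribution, dtype=float)
    reps = params.disease.representative_values
    improvable = 1.0 - e[0]

    if con.responder_fraction_y1 > improvable + RESPONDER_TOL:
        raise InfeasibleConstraints(
            f"responder fraction {con.responder_fraction_y1} unreachable: only "
            f"{improvable:.3f} of the cohort enrolls above category 1")
    r = 0.0 if improvable == 0 else con.responder_fraction_y1 / improvable

    def mean_change(theta: float) -> float:
        out = e @ _year1_matrix(theta, r)
        return float((out - e) @ reps)

    if con.two_category_fraction is not None:
        theta = float(con.two_category_fraction)
        resid = mean_change(theta) - con.mean_change_y1
        if abs(resid) > MEAN_TOL:
            raise InfeasibleConstraints(
                f"fixed two-category fraction {theta} implies mean change "
                f"{mean_change(theta):.4f}, target {con.mean_change_y1}")
    else:
        strongest, weakest = mean_change(2.0), mean_change(-1.0)
        target = con.mean_change_y1
        if not (strongest - MEAN_TOL <= target <= weakest + MEAN_TOL):
            raise InfeasibleConstraints(
                f"mean change {target} {params.disease.units} unreachable from "
                f"enrollment {e.tolist()} with responder fraction "
                f"{con.responder_fraction_y1}: achievable range "
                f"[{strongest:.4f}, {weakest:.4f}]")
        target = min(max(target, strongest), weakest)   # tolerance-edge safety
        if abs(weakest - strongest) < 1e-15:
            theta = 0.0
        else:
            theta = brentq(lambda t: mean_change(t) - target, -1.0, 2.0, xtol=1e-13)

    table = TransitionTable(
        year1=_year1_matrix(theta, r),
        later={2: _later_matrix(con.y2_improvement, con.category4_damping),
               3: _later_matrix(con.y3_improvement, con.category4_damping)},
        responder_fraction=con.responder_fraction_y1,
        mean_change=con.mean_change_y1,
    )
    table.validate()
    assert abs(table.implied_responder_fraction(e) - con.responder_fraction_y1) < 1e-9
    assert abs(table.implied_mean_change(e, reps) - con.mean_change_y1) < MEAN_TOL * 10
    return table


# ---------------------------------------------------------------------------
# Randomized parameter sets
# ---------------------------------------------------------------------------

def random_parameter_set(disease: str, seed: int, max_tries: int = 100) -> ModelParameters:
    """Every sensitivity-analysis parameter drawn uniformly within its range;
    always valid and synthesizable (draws whose effectiveness pair is
    infeasible for the table ansatz are rejected and redrawn)."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        params = default_parameters(disease)
        for entry in sa_registry(params):
            lo = entry.bound_value(params, "low")
            hi = entry.bound_value(params, "high")
            entry.setter(params, float(rng.uniform(min(lo, hi), max(lo, hi))))
        params.transition_tables = None
        params.validate()
        try:
            params.transition_tables = synthesize_transition_tables(params)
            return params
        except InfeasibleConstraints:
            continue
    raise InfeasibleConstraints(f"no feasible parameter draw in {max_tries} tries")


# ---------------------------------------------------------------------------
# Microsimulation oracle
# ---------------------------------------------------------------------------

@dataclass
class MicrosimResult:
    """Empirical per-enrollee aggregates from individual-level simulation."""

    n_patients: int
    retained: np.ndarray                 # end-of-year program retention, years 1-3
    arm_costs: dict[str, np.ndarray]     # undiscounted totals per year
    arm_costs_se: dict[str, np.ndarray]
    pppm: np.ndarray                     # yearly savings per enrolled month
    pppm_se: np.ndarray
    delta_cost: float                    # discounted 3-year HRU saving
    delta_cost_se: float
    delta_qaly: float
    delta_qaly_se: float
    active_distributions: np.ndarray     # (3, 4) empirical, active participants


def _sample_rows(prob_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row of an (n, 4) probability matrix."""
    cum = np.cumsum(prob_rows, axis=1)
    u = rng.random(prob_rows.shape[0])[:, None]
    return np.minimum((u > cum).sum(axis=1), 3)


def microsimulate(params: ModelParameters, n_patients: int, seed: int) -> MicrosimResult:
    """Per-patient paths sampled from the same transition rows, attrition
    schedule, delay proration and discounting as the deterministic engine;
    costs and QALYs are accumulated as conditional expectations given each
    sampled path, so aggregates converge to the cohort solution."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    from .cea import utility_vector
    from .costs import comorbid_med_vector, cvd_rate_vector, disease_med_vector

    rng = np.random.default_rng(seed)
    n = int(n_patients)
    e = np.asarray(params.enrollment_distribution, dtype=float)
    table = _cohort._require_tables(params)
    Mtau = _cohort.tau_transition_matrix(params.tau_persistence, params.tau_spill_rule)
    sched = params.attrition

    com_v = comorbid_med_vector(params)
    cost_v = {
        True: disease_med_vector(params, True) + com_v
        + cvd_rate_vector(params, True) * params.cvd_event_cost,
        False: disease_med_vector(params, False) + com_v
        + cvd_rate_vector(params, False) * params.cvd_event_cost,
    }
    util_v = {
        True: utility_vector(params, True)
        + cvd_rate_vector(params, True) * params.utilities.cvd_event_increment,
        False: utility_vector(params, False)
        + cvd_rate_vector(params, False) * params.utilities.cvd_event_increment,
    }
    # year-1 delay blending of the active stratum, per category pair
    fm = params.delays.medication_delay_months / 12.0
    fc = params.delays.cvd_delay_months / 12.0
    med_pre, med_post = disease_med_vector(params, False) + com_v, disease_med_vector(params, True) + com_v
    cvd_pre = cvd_rate_vector(params, False) * params.cvd_event_cost
    cvd_post = cvd_rate_vector(params, True) * params.cvd_event_cost

    enroll_cat = _sample_rows(np.tile(e, (n, 1)), rng)

    def tau_year():
        return _sample_rows(Mtau[enroll_cat], rng)

    # program attrition path
    early = rng.random(n) < sched.y1_early
    late = ~early & (rng.random(n) < sched.y1_late)
    active1 = ~early                                   # in program past month 3
    active_end1 = active1 & ~late
    wd2 = active_end1 & (rng.random(n) < sched.y2)
    active_end2 = active_end1 & ~wd2
    wd3 = active_end2 & (rng.random(n) < sched.y3)
    active_end3 = active_end2 & ~wd3

    # category paths for program participants
    cat1 = _sample_rows(table.year1[enroll_cat], rng)
    M2, M3 = table.matrix_for_year(2), table.matrix_for_year(3)
    cat2 = _sample_rows(M2[enroll_cat, cat1], rng)
    cat3 = _sample_rows(M3[enroll_cat, cat2], rng)

    dtx_cost = np.zeros((n, 3))
    dtx_util = np.zeros((n, 3))
    # year 1
    dtx_cost[early, 0] = cost_v[False][enroll_cat[early]]
    dtx_util[early, 0] = util_v[False][enroll_cat[early]]
    a = active1
    dtx_cost[a, 0] = (fm * med_pre[enroll_cat[a]] + (1 - fm) * med_post[cat1[a]]
                      + fc * cvd_pre[enroll_cat[a]] + (1 - fc) * cvd_post[cat1[a]])
    dtx_util[a, 0] = (fm * (utility_vector(params, False)[enroll_cat[a]])
                      + (1 - fm) * (utility_vector(params, True)[cat1[a]])
                      + (fc * cvd_rate_vector(params, False)[enroll_cat[a]]
                         + (1 - fc) * cvd_rate_vector(params, True)[cat1[a]])
                      * params.utilities.cvd_event_increment)
    # years 2 and 3
    half = sched.y23_month / 12.0
    for yi, (act, wd, cat_now, cat_prev) in enumerate(
            ((active_end2, wd2, cat2, cat1),
             (active_end3, wd3, cat3, cat2)), start=1):
        tau_cat = tau_year()
        out_of_program = ~(act | wd)
        dtx_cost[out_of_program, yi] = cost_v[False][tau_cat[out_of_program]]
        dtx_util[out_of_program, yi] = util_v[False][tau_cat[out_of_program]]
        dtx_cost[act, yi] = cost_v[True][cat_now[act]]
        dtx_util[act, yi] = util_v[True][cat_now[act]]
        dtx_cost[wd, yi] = (half * cost_v[True][cat_prev[wd]]
                            + (1 - half) * cost_v[False][tau_cat[wd]])
        dtx_util[wd, yi] = (half * util_v[True][cat_prev[wd]]
                            + (1 - half) * util_v[False][tau_cat[wd]])

    tau_cost = np.zeros((n, 3))
    tau_util = np.zeros((n, 3))
    for yi in range(3):
        c = tau_year()
        tau_cost[:, yi] = cost_v[False][c]
        tau_util[:, yi] = util_v[False][c]

    df = 1.0 / (1.0 + params.discount_rate) ** np.arange(3)
    sav = tau_cost - dtx_cost
    dq = (dtx_util - tau_util) @ df
    dcost = sav @ df

    retained = np.array([active_end1.mean(), active_end2.mean(), active_end3.mean()])
    active_masks = (active_end1, active_end2, active_end3)
    cats = (cat1, cat2, cat3)
    active_dists = np.stack([
        np.bincount(cats[i][active_masks[i]], minlength=4) / max(active_masks[i].sum(), 1)
        for i in range(3)])

    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n))
    return MicrosimResult(
        n_patients=n,
        retained=retained,
        arm_costs={"TAU": tau_cost.mean(axis=0), "DTX_TAU": dtx_cost.mean(axis=0)},
        arm_costs_se={"TAU": tau_cost.std(axis=0, ddof=1) / np.sqrt(n),
                      "DTX_TAU": dtx_cost.std(axis=0, ddof=1) / np.sqrt(n)},
        pppm=sav.mean(axis=0) / 12.0,
        pppm_se=sav.std(axis=0, ddof=1) / np.sqrt(n) / 12.0,
        delta_cost=float(dcost.mean()), delta_cost_se=sem(dcost),
        delta_qaly=float(dq.mean()), delta_qaly_se=sem(dq),
        active_distributions=active_dists,
    )
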