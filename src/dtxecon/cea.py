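"""QALYs, incremental cost effectiveness, and break-even program-cost
threshold curves.

Cost effectiveness is judged by net monetary benefit: at willingness-to-pay
lambda, a 3-year program cost C (treated as an upfront per-enrollee total) is
cost effective iff C <= breakeven(lambda) = delta_HRU_savings + lambda *
delta_QALY, an affine function of lambda by construction.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortTrajectory, Segment
from .costs import AnnualCostBreakdown, cvd_rate_vector, discount, savings_by_year
from .parameters import ModelParameters, UtilitySet

DEFAULT_WTP_GRID = tuple(range(0, 160_000, 10_000))


def state_utility(category: int, on_medications: bool, cvd_event: bool,
                  utilities: UtilitySet) -> float:
    """Utility of one health state: the category-2-without-medications anchor
    plus the applicable increments, clamped to [0, 1]."""
    return utilities.utility(category, on_medications=on_medications, cvd_event=cvd_event)


def utility_vector(params: ModelParameters, dtx_active: bool) -> np.ndarray:
    """Expected utility per category for one arm/status (category 1 carries
    no primary-disease medications; the DTx-arm category-2 unmedicated share
    gets the no-medication utility)."""
    u = params.utilities
    uf = params.cat2_unmedicated_fraction if dtx_active else 0.0
    cat2 = (1.0 - uf) * u.utility(2, on_medications=True) + uf * u.utility(2, on_medications=False)
    return np.array([u.utility(1, on_medications=False), cat2,
                     u.utility(3), u.utility(4)])


def _segment_qaly(seg: Segment, params: ModelParameters, vectors: dict) -> float:
    status = "dtx" if seg.dtx_active else "tau"
    u_v, cvd_v = vectors[status]
    dec = params.utilities.cvd_event_increment
    if seg.delayed_from is None:
        d = seg.distribution
        return float(d @ u_v + (d @ cvd_v) * dec)
    # same mid-year proration as cost accrual: no-medication utility (and CVD
    # risk reduction) only after the respective delays in year 1
    u_tau, cvd_tau = vectors["tau"]
    fm = params.delays.medication_delay_months / 12.0
    fc = params.delays.cvd_delay_months / 12.0
    pre, post = seg.delayed_from, seg.distribution
    base = fm * (pre @ u_tau) + (1.0 - fm) * (post @ u_v)
    event = (fc * (pre @ cvd_tau) + (1.0 - fc) * (post @ cvd_v)) * dec
    return float(base + event)


def arm_qalys(trajectory: CohortTrajectory, params: ModelParameters,
              by_year: bool = False):
    """Discounted QALYs per original enrollee over the horizon, weighting
    active and withdrawn strata by occupancy and medication status, with the
    expected CVD-event disutility accrued in the event year."""
    vectors = {
        "dtx": (utility_vector(params, True), cvd_rate_vector(params, True)),
        "tau": (utility_vector(params, False), cvd_rate_vector(params, False)),
    }
    per_year = np.zeros(3)
    for y in (1, 2, 3):
        for seg in trajectory.years[y].segments:
            per_year[y - 1] += seg.mass * seg.year_fraction * _segment_qaly(seg, params, vectors)
    disc = discount(per_year, np.arange(1, 4), params.discount_rate)
    return disc if by_year else float(disc.sum())


@dataclass
class CEAResult:
    """Incremental result of DTx + TAU vs TAU alone, per original enrollee.

    ``delta_cost_savings`` is the discounted 3-year HRU saving (program cost
    excluded); ``breakeven(wtp)`` is the maximum upfront 3-year program cost
    that is cost effective at that willingness-to-pay.
    """

    delta_cost_savings: float
    delta_qaly: float

    def breakeven(self, wtp: float) -> float:
        return self.delta_cost_savings + wtp * self.delta_qaly

    def net_monetary_benefit(self, program_cost: float, wtp: float) -> float:
        return self.breakeven(wtp) - program_cost

    def cost_effective(self, program_cost: float, wtp: float) -> bool:
        return program_cost <= self.breakeven(wtp)


def incremental(tau_costs: AnnualCostBreakdown, dtx_costs: AnnualCostBreakdown,
                tau_qalys: float, dtx_qalys: float) -> CEAResult:
    savings = float(savings_by_year(tau_costs, dtx_costs, discounted=True).sum())
    return CEAResult(delta_cost_savings=savings, delta_qaly=float(dtx_qalys - tau_qalys))


def threshold_curve(result: CEAResult, wtp_grid=DEFAULT_WTP_GRID) -> pd.DataFrame:
    """Tabulated break-even program cost over a willingness-to-pay grid."""
    grid = np.asarray(list(wtp_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    return pd.DataFrame({"wtp_per_qaly": grid,
                         "breakeven_program_cost": [result.breakeven(w) for w in grid]})
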