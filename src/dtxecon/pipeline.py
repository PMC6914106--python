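"""End-to-end model run: trajectories, costs, QALYs, PPPM savings, CEA."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import CEAResult, arm_qalys, incremental, threshold_curve
from .cohort import CohortTrajectory, simulate_cohort
from .costs import AnnualCostBreakdown, arm_costs, pppm_savings, savings_by_year
from .parameters import ModelParameters


@dataclass
class ModelRun:
    """All outputs of one deterministic model evaluation."""

    params: ModelParameters
    trajectories: dict[str, CohortTrajectory]
    costs: dict[str, AnnualCostBreakdown]
    qalys: dict[str, float]
    pppm: np.ndarray            # nominal yearly savings per participant-month
    cea: CEAResult

    @property
    def pppm_average(self) -> float:
        return float(self.pppm.mean())

    def pppm_frame(self) -> pd.DataFrame:
        rows = [{"year": y, "pppm_savings": self.pppm[y - 1]} for y in (1, 2, 3)]
        rows.append({"year": "3-year average", "pppm_savings": self.pppm_average})
        return pd.DataFrame(rows)

    def threshold_frame(self, wtp_grid=None) -> pd.DataFrame:
        from .cea import DEFAULT_WTP_GRID

        return threshold_curve(self.cea, wtp_grid or DEFAULT_WTP_GRID)

    def savings(self, discounted: bool = False) -> np.ndarray:
        return savings_by_year(self.costs["TAU"], self.costs["DTX_TAU"], discounted)


def run_model(params: ModelParameters) -> ModelRun:
    """Simulate both arms and derive every downstream quantity."""
    params.validate()
    trajectories = {arm: simulate_cohort(params, arm) for arm in ("TAU", "DTX_TAU")}
    costs = {arm: arm_costs(traj, params) for arm, traj in trajectories.items()}
    qalys = {arm: arm_qalys(traj, params) for arm, traj in trajectories.items()}
    pppm = np.array([
        pppm_savings(costs["TAU"], costs["DTX_TAU"], y, params.pppm_denominator)
        for y in (1, 2, 3)])
    cea = incremental(costs["TAU"], costs["DTX_TAU"], qalys["TAU"], qalys["DTX_TAU"])
    return ModelRun(params=params, trajectories=trajectories, costs=costs,
                    qalys=qalys, pppm=pppm, cea=cea)
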