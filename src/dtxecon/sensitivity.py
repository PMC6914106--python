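"""One-way deterministic sensitivity analysis (tornado) and named scenario
runs."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ModelParameters, ParameterError, apply_sa_bound, sa_registry
from .pipeline import ModelRun, run_model

OUTCOMES = ("pppm_y1", "pppm_y2", "pppm_y3", "breakeven_50k")

#: Named scenarios: enrollment re-weighted over a category subset, with the
#: base-case transition tables retained (the intervention's per-category
#: effect does not depend on who enrolls).  "high_cost_high_effectiveness"
#: is the 0%-category-2 severity restriction described with the tornado
#: analysis.
SCENARIOS = {
    "severity_34_only": (3, 4),
    "severity_4_only": (4,),
    "high_cost_high_effectiveness": (3, 4),
}


def outcome_value(run: ModelRun, outcome: str) -> float:
    if outcome in ("pppm_y1", "pppm_y2", "pppm_y3"):
        return float(run.pppm[int(outcome[-1]) - 1])
    if outcome == "breakeven_50k":
        return run.cea.breakeven(50_000.0)
    if outcome == "breakeven_100k":
        return run.cea.breakeven(100_000.0)
    if outcome == "pppm_avg":
        return run.pppm_average
    raise ParameterError(f"unknown outcome {outcome!r}; known: {OUTCOMES}")


@dataclass
class SAResult:
    parameter_name: str
    low_value: float
    high_value: float
    outcome_low: float
    outcome_high: float
    base_outcome: float

    @property
    def span(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def one_way_sa(params: ModelParameters, outcome: str = "pppm_y1",
               parameter_list: list[str] | None = None) -> list[SAResult]:
    """Two full model runs per parameter (each bound, all else at base),
    sorted by outcome span descending.  The input parameter object is never
    modified."""
    base_run = run_model(params.copy())
    base = outcome_value(base_run, outcome)
    entries = sa_registry(params)
    if parameter_list is not None:
        known = {e.name for e in entries}
        unknown = set(parameter_list) - known
        if unknown:
            raise ParameterError(f"no sensitivity range declared for {sorted(unknown)}")
        entries = [e for e in entries if e.name in set(parameter_list)]
    results = []
    for entry in entries:
        vals = {}
        outs = {}
        for direction in ("low", "high"):
            perturbed = apply_sa_bound(params, entry.name, direction)
            vals[direction] = entry.bound_value(params, direction)
            outs[direction] = outcome_value(run_model(perturbed), outcome)
        results.append(SAResult(entry.name, vals["low"], vals["high"],
                                outs["low"], outs["high"], base))
    results.sort(key=lambda r: -r.span)
    return results


def tornado_frame(results: list[SAResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"rank": i + 1, "parameter": r.parameter_name,
         "low": r.low_value, "high": r.high_value,
         "outcome_low": r.outcome_low, "outcome_high": r.outcome_high,
         "base_outcome": r.base_outcome, "span": r.span}
        for i, r in enumerate(results)])


def restrict_enrollment(params: ModelParameters, categories: tuple[int, ...]) -> ModelParameters:
    """Re-weight the enrollment distribution over a subset of categories,
    keeping the (base-synthesized) transition tables."""
    from .cohort import _require_tables

    out = params.copy()
    _require_tables(out)   # pin tables to the base enrollment before re-weighting
    e = np.zeros(4)
    for c in categories:
        e[c - 1] = params.enrollment_distribution[c - 1]
    if e.sum() <= 0:
        raise ParameterError(f"no enrollment mass in categories {categories}")
    out.enrollment_distribution = e / e.sum()
    return out.validate()


def scenario_run(params: ModelParameters, overrides=None) -> ModelRun:
    """Run the model under a named scenario or an explicit override map.

    ``overrides`` may be a scenario name from :data:`SCENARIOS`, a mapping of
    ``ModelParameters`` field names to values, or None/empty (base case).
    """
    if not overrides:
        return run_model(params.copy())
    if isinstance(overrides, str):
        if overrides not in SCENARIOS:
            raise ParameterError(f"unknown scenario {overrides!r}; known: {sorted(SCENARIOS)}")
        return run_model(restrict_enrollment(params, SCENARIOS[overrides]))
    out = params.copy(**dict(overrides))
    return run_model(out.validate())
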