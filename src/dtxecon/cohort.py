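"""Cohort evolution through the 3-year two-arm decision tree.

The DTx + TAU arm is tracked stratified by enrollment category (a 4x4 state
whose rows are enrollment categories), which carries the assumption that
patients enrolled in category 4 respond less in later years.  Attrition moves
mass into withdrawn strata whose category distributions follow the return
rules: year-1 withdrawers to their enrollment values, year-2/3 withdrawers to
the average TAU-alone outcome.  The TAU-alone arm keeps full mass (attrition
is from the program, not the health plan) and is stable: the persistence
transition is applied to the enrollment distribution each year.

Each trajectory year exposes a list of costing segments -- (mass, fraction of
the year, category distribution, DTx-active flag, optional delay-blended
pre/post distributions) -- which the cost and QALY engines consume without
re-deriving timing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    AttritionSchedule,
    DiseaseSpec,
    ModelParameters,
    ParameterError,
    TransitionTable,
    get_disease,
)

DIST_TOL = 1e-9


def classify_biomarker(disease: str | DiseaseSpec, value: float) -> int:
    """Outcome category 1-4 for a biomarker value.

    Categories are left-closed on the printed lower bound (HbA1c 6.5 ->
    category 2, SBP 120 -> category 2, SBP 140 -> category 4); for T2DM the
    printed "7.5% to 9.0%" wording closes category 3 on the right, so HbA1c
    9.0 -> category 3.
    """
    d = get_disease(disease)
    if not math.isfinite(value):
        raise ValueError(f"biomarker value must be finite, got {value}")
    if value <= 0:
        raise ValueError(f"biomarker value must be positive, got {value}")
    b1, b2, b3 = d.category_bounds
    if value < b1:
        return 1
    if value < b2:
        return 2
    if value <= b3 if d.cat3_upper_closed else value < b3:
        return 3
    return 4


def _check_distribution(dist: np.ndarray, where: str = "distribution") -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.shape != (4,):
        raise ParameterError(f"{where} must have 4 entries")
    if (dist < -DIST_TOL).any() or abs(dist.sum() - 1.0) > DIST_TOL:
        raise ParameterError(f"{where} is not a probability distribution: {dist}")
    return dist


def tau_transition_matrix(persistence: float, spill_rule: str = "symmetric_adjacent") -> np.ndarray:
    """Row-stochastic TAU transition: ``persistence`` mass on the diagonal,
    the rest split between adjacent categories (reflecting inward at the
    ends), or kept in place under the degenerate ``'stay'`` rule."""
    if not (0.0 <= persistence <= 1.0):
        raise ParameterError(f"persistence must be in [0, 1], got {persistence}")
    spill = 1.0 - persistence
    M = np.eye(4) * persistence
    if spill_rule == "stay":
        M += np.eye(4) * spill
    elif spill_rule == "symmetric_adjacent":
        M[0, 1] += spill
        M[3, 2] += spill
        for c in (1, 2):
            M[c, c - 1] += spill / 2.0
            M[c, c + 1] += spill / 2.0
    else:
        raise ParameterError(f"unknown spill rule {spill_rule!r}")
    return M


def tau_transition(current: np.ndarray, persistence: float,
                   spill_rule: str = "symmetric_adjacent") -> np.ndarray:
    """One TAU-alone year applied to a category distribution."""
    cur = _check_distribution(current, "current distribution")
    return cur @ tau_transition_matrix(persistence, spill_rule)


def dtx_transition(current: np.ndarray, year: int, table: TransitionTable,
                   enrollment_category: int | None = None) -> np.ndarray:
    """One DTx-arm year: matrix-vector product with the year's transition rows.

    Years 2-3 are stratified by enrollment category; pass
    ``enrollment_category`` to select the stratum (default: category-2
    stratum dynamics, which years 2-3 share with category 3).
    """
    cur = _check_distribution(current, "current distribution")
    if year == 1:
        return cur @ table.year1
    M = table.matrix_for_year(year)
    c = 1 if enrollment_category is None else enrollment_category - 1
    return cur @ M[c]


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Segment:
    """Exposure of one cohort stratum during part of one year."""

    mass: float                   # fraction of original enrollees
    year_fraction: float
    distribution: np.ndarray
    dtx_active: bool
    # year-1 clinical-inertia blending: costed on pre_distribution (at TAU
    # medication status) until the relevant delay elapses, then on
    # ``distribution`` at DTx status
    delayed_from: np.ndarray | None = None


@dataclass
class YearState:
    year: int
    retained_fraction: float
    active_state: np.ndarray          # (4, 4): enrollment stratum x category
    active_distribution: np.ndarray   # aggregate over strata
    withdrawn_distribution: np.ndarray | None
    new_withdrawn_mass: float
    withdrawal_month: float | None
    segments: list[Segment] = field(default_factory=list)


@dataclass
class CohortTrajectory:
    arm: str
    disease: str
    enrollment: np.ndarray
    years: dict[int, YearState]

    def retained(self) -> np.ndarray:
        return np.array([self.years[y].retained_fraction for y in sorted(self.years)])

    def mass_check(self) -> None:
        """Conservation: retained + withdrawn strata account for everyone."""
        for y, st in self.years.items():
            mass = sum(s.mass * s.year_fraction for s in st.segments)
            if abs(mass - 1.0) > 1e-9:
                raise AssertionError(f"year {y}: segment mass {mass} != 1")


def attrition_masses(schedule: AttritionSchedule, horizon: int = 3):
    """Per-year (retained_end, newly_withdrawn, withdrawal_month) implied by
    the schedule.  Year 1 pools the month-3 and year-end withdrawals."""
    retained = schedule.retained_by_year()
    rates = [None, schedule.y2, schedule.y3]
    out = []
    prev = 1.0
    for y in (1, 2, 3):
        r = retained[y - 1]
        month = schedule.y1_early_month if y == 1 else schedule.y23_month
        out.append((float(r), float(prev - r), float(month)))
        prev = r
    return out[:horizon]


def apply_attrition(trajectory: CohortTrajectory, schedule: AttritionSchedule, year: int,
                    tau_distribution: np.ndarray) -> CohortTrajectory:
    """Move the year's scheduled withdrawal mass into the withdrawn stratum
    with its distribution set by the year's return rule, scaling
    ``retained_fraction`` multiplicatively.  (The simulation applies this
    internally; exposed for direct use and testing.)"""
    st = trajectory.years[year]
    masses = attrition_masses(schedule)[year - 1]
    st.retained_fraction = masses[0]
    st.new_withdrawn_mass = masses[1]
    st.withdrawal_month = masses[2]
    st.withdrawn_distribution = (
        trajectory.enrollment.copy() if year == 1 else np.asarray(tau_distribution, dtype=float))
    return trajectory


def _require_tables(params: ModelParameters) -> TransitionTable:
    if params.transition_tables is not None:
        return params.transition_tables
    if not params.allow_synthesis:
        raise ParameterError(
            "transition_tables are not set and allow_synthesis is false; "
            "provide 'transition_tables' in the config or enable synthesis")
    from .synthesis import synthesize_transition_tables

    params.transition_tables = synthesize_transition_tables(params)
    return params.transition_tables


def simulate_cohort(params: ModelParameters, arm: str) -> CohortTrajectory:
    """Deterministic 3-year trajectory for one arm.

    DTx + TAU: year-1 table applied to the enrollment distribution; month-3
    withdrawers carry enrollment values all year, year-end withdrawers accrue
    active (delay-gated) membership during year 1 and revert at year end;
    year-2/3 withdrawers leave mid-year, half a year at the previous year-end
    distribution and half at the TAU average, joining the TAU pool thereafter.
    TAU alone: full mass at the persistence transition of enrollment, every
    year.
    """
    if arm not in ("DTX_TAU", "TAU"):
        raise ParameterError(f"arm must be 'DTX_TAU' or 'TAU', got {arm!r}")
    e = _check_distribution(params.enrollment_distribution, "enrollment distribution")
    Mtau = tau_transition_matrix(params.tau_persistence, params.tau_spill_rule)
    tau_state = (e[:, None] * Mtau)          # stratified, rows sum to e
    tau_dist = e @ Mtau

    years: dict[int, YearState] = {}

    if arm == "TAU":
        for y in (1, 2, 3):
            years[y] = YearState(
                year=y, retained_fraction=1.0,
                active_state=tau_state, active_distribution=tau_dist,
                withdrawn_distribution=None, new_withdrawn_mass=0.0, withdrawal_month=None,
                segments=[Segment(1.0, 1.0, tau_dist, dtx_active=False)])
        return CohortTrajectory(arm=arm, disease=params.disease.key, enrollment=e, years=years)

    table = _require_tables(params)
    sched = params.attrition
    masses = attrition_masses(sched)

    # normalized stratified state of active participants (rows: enrollment cat)
    S1 = e[:, None] * table.year1            # sums to 1 (withdrawal is category-blind)
    d1 = S1.sum(axis=0)
    M2, M3 = table.matrix_for_year(2), table.matrix_for_year(3)
    S2 = np.stack([S1[c] @ M2[c] for c in range(4)])
    d2 = S2.sum(axis=0)
    S3 = np.stack([S2[c] @ M3[c] for c in range(4)])
    d3 = S3.sum(axis=0)

    r1, w1, m1 = masses[0]
    r2, w2, m2_month = masses[1]
    r3, w3, m3_month = masses[2]
    survivors_y1 = 1.0 - sched.y1_early      # in program past month 3

    years[1] = YearState(
        year=1, retained_fraction=r1, active_state=S1, active_distribution=d1,
        withdrawn_distribution=e.copy(), new_withdrawn_mass=w1, withdrawal_month=m1,
        segments=[
            Segment(sched.y1_early, 1.0, e.copy(), dtx_active=False),
            Segment(survivors_y1, 1.0, d1, dtx_active=True, delayed_from=e.copy()),
        ])

    pool2 = 1.0 - r1                          # year-1 withdrawers, now TAU-like
    years[2] = YearState(
        year=2, retained_fraction=r2, active_state=S2, active_distribution=d2,
        withdrawn_distribution=tau_dist, new_withdrawn_mass=w2, withdrawal_month=m2_month,
        segments=[
            Segment(r2, 1.0, d2, dtx_active=True),
            Segment(w2, m2_month / 12.0, d1, dtx_active=True),
            Segment(w2, 1.0 - m2_month / 12.0, tau_dist, dtx_active=False),
            Segment(pool2, 1.0, tau_dist, dtx_active=False),
        ])

    pool3 = pool2 + w2
    years[3] = YearState(
        year=3, retained_fraction=r3, active_state=S3, active_distribution=d3,
        withdrawn_distribution=tau_dist, new_withdrawn_mass=w3, withdrawal_month=m3_month,
        segments=[
            Segment(r3, 1.0, d3, dtx_active=True),
            Segment(w3, m3_month / 12.0, d2, dtx_active=True),
            Segment(w3, 1.0 - m3_month / 12.0, tau_dist, dtx_active=False),
            Segment(pool3, 1.0, tau_dist, dtx_active=False),
        ])

    traj = CohortTrajectory(arm=arm, disease=params.disease.key, enrollment=e, years=years)
    traj.mass_check()
    return traj
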