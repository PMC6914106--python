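"""Model parameters for the digital-therapeutic (DTx) economic models.

Two disease models share one structure: a cohort classified into four
biomarker categories (HbA1c for type 2 diabetes, systolic blood pressure for
hypertension), a DTx + treatment-as-usual (TAU) arm compared with TAU alone
over a 3-year horizon, program attrition, category-gradient medication costs,
CVD event costs, health-state utilities, and clinical-inertia delays before
economic benefits are realized.

This module houses every base-case parameter, the one-way sensitivity-analysis
(SA) ranges, validation, and YAML config load/serialize.  A few quantities the
published tables do not print are shipped as *calibrated placeholders* (see
``CALIBRATED`` and docs/methods.md): the baseline CVD event rate behind the
T2DM hazard ratios, a scale mapping Framingham 10-year general-CVD risk to
payer-borne event costs in HTN, and the year-2/3 incremental improvement
fractions.
"""
from __future__ import annotations

import copy as _copy
import dataclasses
import io
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger("dtxecon")

N_CATEGORIES = 4
ARMS = ("DTX_TAU", "TAU")


class ParameterError(ValueError):
    """A model parameter violates its declared invariants."""


# ---------------------------------------------------------------------------
# Disease definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiseaseSpec:
    """Biomarker axis and category cut-points for one disease model.

    ``category_bounds`` are the three ordered cut-points separating outcome
    categories 1-4.  ``cat3_upper_closed`` encodes the boundary convention:
    for T2DM category 3 is 7.5-9.0% inclusive (9.0 -> category 3), while for
    HTN 140 mm Hg already belongs to category 4.  ``representative_floor`` /
    ``representative_cap`` close the open-ended outer bins so that category
    midpoints (used as representative biomarker values) are finite.
    """

    key: str
    label: str
    biomarker: str
    units: str
    category_bounds: tuple[float, float, float]
    cat3_upper_closed: bool
    representative_floor: float
    representative_cap: float

    def __post_init__(self) -> None:
        b = self.category_bounds
        if not (b[0] < b[1] < b[2]):
            raise ParameterError(f"category_bounds must be strictly increasing, got {b}")
        if not (self.representative_floor < b[0] and self.representative_cap > b[2]):
            raise ParameterError("representative floor/cap must bracket the category bounds")

    @property
    def representative_values(self) -> np.ndarray:
        """Midpoint biomarker value per category, outer bins floored/capped."""
        edges = [self.representative_floor, *self.category_bounds, self.representative_cap]
        return np.array([(edges[i] + edges[i + 1]) / 2.0 for i in range(4)])


T2DM = DiseaseSpec(
    key="t2dm",
    label="Type 2 diabetes mellitus",
    biomarker="HbA1c",
    units="%",
    category_bounds=(6.5, 7.5, 9.0),
    cat3_upper_closed=True,
    representative_floor=5.5,
    representative_cap=12.0,
)

# SBP cap 160 (representative 150 mm Hg, a stage-2 cohort mean): with a higher
# cap the printed year-1 responder fraction and mean SBP change are jointly
# unattainable by any category-move table (see docs/methods.md).
HTN = DiseaseSpec(
    key="htn",
    label="Hypertension",
    biomarker="SBP",
    units="mm Hg",
    category_bounds=(120.0, 130.0, 140.0),
    cat3_upper_closed=False,
    representative_floor=110.0,
    representative_cap=160.0,
)

DISEASES: dict[str, DiseaseSpec] = {"t2dm": T2DM, "htn": HTN}


def get_disease(identifier: str | DiseaseSpec) -> DiseaseSpec:
    if isinstance(identifier, DiseaseSpec):
        return identifier
    key = str(identifier).strip().lower()
    if key not in DISEASES:
        raise ParameterError(f"unknown disease identifier {identifier!r}; expected one of {sorted(DISEASES)}")
    return DISEASES[key]


# ---------------------------------------------------------------------------
# Component parameter blocks
# ---------------------------------------------------------------------------

@dataclass
class AttritionSchedule:
    """DTx program attrition: 20% at month 3 of year 1 (no engagement or no
    improvement), a further 20% of the remainder at year-1 end (improvement
    not durable), and 10% during each of years 2 and 3.

    Year-1 withdrawers return to their enrollment values; later withdrawers
    return to the average TAU-alone outcome for the year.
    """

    y1_early: float = 0.20
    y1_late: float = 0.20
    y2: float = 0.10
    y3: float = 0.10
    y1_early_month: float = 3.0
    y23_month: float = 6.0   # mid-year timing for year-2/3 withdrawals
    y1_return_rule: str = "to_enrollment"
    y23_return_rule: str = "to_tau_average"

    def validate(self) -> None:
        for name in ("y1_early", "y1_late", "y2", "y3"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"attrition.{name} must be in [0, 1], got {v}")
        for name, hi in (("y1_early_month", 12.0), ("y23_month", 12.0)):
            v = getattr(self, name)
            if not (0.0 <= v <= hi):
                raise ParameterError(f"attrition.{name} must be in [0, {hi}], got {v}")
        if self.y1_return_rule != "to_enrollment":
            raise ParameterError(f"unsupported y1_return_rule {self.y1_return_rule!r}")
        if self.y23_return_rule != "to_tau_average":
            raise ParameterError(f"unsupported y23_return_rule {self.y23_return_rule!r}")

    def retained_by_year(self) -> np.ndarray:
        """Fraction of original enrollees active in the program at the end of
        years 1..3 (base case: 0.64, 0.576, 0.5184)."""
        r1 = (1.0 - self.y1_early) * (1.0 - self.y1_late)
        r2 = r1 * (1.0 - self.y2)
        return np.array([r1, r2, r2 * (1.0 - self.y3)])


@dataclass
class CostGradient:
    """Annual medication cost by outcome category: base cost times a
    non-decreasing slope per category (slope 0 = class not used)."""

    base_annual_cost: float
    slopes: tuple[float, float, float, float]

    def validate(self, name: str = "gradient") -> None:
        if self.base_annual_cost < 0:
            raise ParameterError(f"{name}.base_annual_cost must be >= 0")
        s = self.slopes
        if len(s) != 4 or any(x < 0 for x in s):
            raise ParameterError(f"{name}.slopes must be 4 non-negative values, got {s}")
        if any(s[i] > s[i + 1] for i in range(3)):
            raise ParameterError(f"{name}.slopes must be non-decreasing across categories, got {s}")

    def annual_cost(self, category: int) -> float:
        return self.base_annual_cost * self.slopes[category - 1]

    def cost_vector(self) -> np.ndarray:
        return self.base_annual_cost * np.asarray(self.slopes, dtype=float)


@dataclass
class UtilitySet:
    """Health-state utilities anchored at category 2 without medications,
    with printed increments for the other states.

    ``increment_mode='absolute'`` (default) reads every increment relative to
    the anchor, exactly as printed.  ``'cumulative'`` chains them
    (cat3 = cat2-on-meds + inc3, cat4 = cat3 + inc4), which restores
    monotonicity across categories at the price of departing from the printed
    arithmetic.
    """

    anchor_utility: float
    cat1_increment: float
    cat2_on_meds_increment: float
    cat3_increment: float
    cat4_increment: float
    cvd_event_increment: float = -0.10
    increment_mode: str = "absolute"

    def validate(self) -> None:
        if self.increment_mode not in ("absolute", "cumulative"):
            raise ParameterError(f"increment_mode must be 'absolute' or 'cumulative', got {self.increment_mode!r}")
        for cat in (1, 2, 3, 4):
            for meds in (False, True):
                u = self.utility(cat, on_medications=meds)
                if not (0.0 <= u <= 1.0):
                    raise ParameterError(f"utility for category {cat} (meds={meds}) out of [0, 1]: {u}")

    def utility(self, category: int, on_medications: bool = True, cvd_event: bool = False) -> float:
        a = self.anchor_utility
        if category == 1:
            u = a + self.cat1_increment
        elif category == 2:
            u = a + (self.cat2_on_meds_increment if on_medications else 0.0)
        elif category == 3:
            u = (a + self.cat2_on_meds_increment + self.cat3_increment
                 if self.increment_mode == "cumulative" else a + self.cat3_increment)
        elif category == 4:
            u = self.utility(3) + self.cat4_increment if self.increment_mode == "cumulative" \
                else a + self.cat4_increment
        else:
            raise ParameterError(f"category must be 1-4, got {category}")
        if cvd_event:
            u += self.cvd_event_increment
        return float(min(1.0, max(0.0, u)))


@dataclass
class DelayParameters:
    """Clinical-inertia delays: months of sustained improvement before
    medications are reduced, and months before CVD risk reduction begins."""

    medication_delay_months: float = 6.0
    cvd_delay_months: float = 3.0

    def validate(self) -> None:
        for name in ("medication_delay_months", "cvd_delay_months"):
            v = getattr(self, name)
            if not (0.0 <= v <= 12.0):
                raise ParameterError(f"delays.{name} must be in [0, 12], got {v}")


@dataclass
class FraminghamAssumptions:
    """Representative risk-profile inputs for the HTN model's Framingham
    general-CVD calculation that the published tables do not print.
    Documented assumptions, exposed in config."""

    total_cholesterol: float = 200.0
    hdl_cholesterol: float = 50.0
    smoking_prevalence: float = 0.14    # US adult current-smoker rate
    female_fraction: float = 0.50

    def validate(self) -> None:
        if self.total_cholesterol <= 0 or self.hdl_cholesterol <= 0:
            raise ParameterError("framingham cholesterol values must be positive")
        for name in ("smoking_prevalence", "female_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"framingham.{name} must be in [0, 1], got {v}")


@dataclass
class SynthesisConstraints:
    """Constraints the synthesized transition tables must satisfy, plus the
    year-2/3 incremental-improvement assumptions (calibrated; unprinted)."""

    responder_fraction_y1: float
    mean_change_y1: float
    y2_improvement: float
    y3_improvement: float
    category4_damping: float = 0.5
    two_category_fraction: float | None = None  # solved if None

    def validate(self) -> None:
        if not (0.0 <= self.responder_fraction_y1 <= 1.0):
            raise ParameterError("synthesis.responder_fraction_y1 must be in [0, 1]")
        for name in ("y2_improvement", "y3_improvement"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"synthesis.{name} must be in [0, 1]")
        if not (0.0 < self.category4_damping <= 1.0):
            raise ParameterError("synthesis.category4_damping must be in (0, 1]")


@dataclass
class TransitionTable:
    """Year-by-year category transitions for active DTx participants.

    ``year1[c, k]`` maps enrollment category c to end-of-year-1 category k.
    ``later[y][c, j, k]`` maps, for enrollment category c, the previous
    year-end category j to the year-y end category k -- the enrollment
    stratification carries the assumption that patients enrolled in category
    4 are more resistant to further improvement.
    """

    year1: np.ndarray
    later: dict[int, np.ndarray]
    responder_fraction: float | None = None
    mean_change: float | None = None

    ROW_TOL = 1e-9

    def validate(self) -> None:
        y1 = np.asarray(self.year1, dtype=float)
        if y1.shape != (4, 4):
            raise ParameterError(f"year1 table must be 4x4, got {y1.shape}")
        self._check_rows(y1, "year 1")
        for y, M in self.later.items():
            M = np.asarray(M, dtype=float)
            if M.shape != (4, 4, 4):
                raise ParameterError(f"year {y} table must be 4x4x4 (enrollment, from, to), got {M.shape}")
            for c in range(4):
                self._check_rows(M[c], f"year {y}, enrollment category {c + 1}")

    @staticmethod
    def _check_rows(M: np.ndarray, where: str) -> None:
        if (M < -TransitionTable.ROW_TOL).any():
            raise ParameterError(f"negative transition probability in {where}")
        bad = np.where(np.abs(M.sum(axis=-1) - 1.0) > TransitionTable.ROW_TOL)[0]
        if bad.size:
            raise ParameterError(
                f"transition rows not stochastic in {where}: row(s) {[int(b) + 1 for b in bad]} "
                f"sum to {M.sum(axis=-1)[bad]}")

    def matrix_for_year(self, year: int) -> np.ndarray:
        """Return the (enrollment, from, to) operator for ``year``."""
        if year == 1:
            # year 1 maps enrollment -> end of year 1; lift to stratified form
            M = np.zeros((4, 4, 4))
            for c in range(4):
                M[c, :, :] = self.year1[c][None, :]
            return M
        if year not in self.later:
            raise ParameterError(f"transition table has no year {year}")
        return np.asarray(self.later[year], dtype=float)

    def implied_responder_fraction(self, enrollment: np.ndarray) -> float:
        """Fraction of the enrolled cohort improving >= 1 category in year 1."""
        e = np.asarray(enrollment, dtype=float)
        improved = sum(e[c] * self.year1[c, :c].sum() for c in range(4))
        return float(improved)

    def implied_mean_change(self, enrollment: np.ndarray, representative_values: np.ndarray) -> float:
        e = np.asarray(enrollment, dtype=float)
        out = e @ self.year1
        return float((out - e) @ np.asarray(representative_values, dtype=float))


# ---------------------------------------------------------------------------
# The full parameter set
# ---------------------------------------------------------------------------

@dataclass
class ModelParameters:
    disease: DiseaseSpec
    mean_age: float
    enrollment_distribution: np.ndarray
    comorbidity_prevalence: dict[str, float]
    med_costs: dict[str, CostGradient]
    cat2_unmedicated_fraction: float
    cvd_event_cost: float
    utilities: UtilitySet
    delays: DelayParameters
    attrition: AttritionSchedule
    synthesis: SynthesisConstraints
    discount_rate: float = 0.03
    horizon_years: int = 3
    tau_persistence: float = 0.80
    tau_spill_rule: str = "symmetric_adjacent"
    # CVD channel: hazard ratios on a baseline rate (T2DM) or Framingham (HTN)
    cvd_hazard_ratios: tuple[float, float, float, float] | None = None
    baseline_cvd_annual_rate: float | None = None
    cvd_rate_scale: float = 1.0
    framingham: FraminghamAssumptions | None = None
    transition_tables: TransitionTable | None = None
    allow_synthesis: bool = True
    pppm_denominator: str = "enrolled_months"   # or "active_months"

    # -- validation ---------------------------------------------------------
    def validate(self) -> "ModelParameters":
        e = np.asarray(self.enrollment_distribution, dtype=float)
        if e.shape != (4,):
            raise ParameterError(f"enrollment_distribution must have 4 entries, got shape {e.shape}")
        if (e < 0).any() or abs(e.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"enrollment_distribution must be a distribution summing to 1, got {e} (sum {e.sum()})")
        if e[0] != 0.0:
            raise ParameterError("enrollment category 1 share must be 0 (no already-optimized patients enrolled)")
        if not (0.0 <= self.discount_rate <= 0.05):
            raise ParameterError(f"discount_rate must be in [0, 0.05], got {self.discount_rate}")
        if self.horizon_years != 3:
            raise ParameterError("horizon_years is fixed at 3 in this model family")
        if not (0.0 <= self.tau_persistence <= 1.0):
            raise ParameterError("tau_persistence must be in [0, 1]")
        if self.tau_spill_rule not in ("symmetric_adjacent", "stay"):
            raise ParameterError(f"unknown tau_spill_rule {self.tau_spill_rule!r}")
        if not (0.0 <= self.cat2_unmedicated_fraction <= 1.0):
            raise ParameterError("cat2_unmedicated_fraction must be in [0, 1]")
        if self.cvd_event_cost < 0:
            raise ParameterError("cvd_event_cost must be >= 0")
        if self.mean_age <= 0:
            raise ParameterError("mean_age must be positive")
        for name, frac in self.comorbidity_prevalence.items():
            if not (0.0 <= frac <= 1.0):
                raise ParameterError(f"comorbidity_prevalence[{name!r}] must be in [0, 1], got {frac}")
        for name, g in self.med_costs.items():
            g.validate(name=f"med_costs[{name!r}]")
        if self.cvd_hazard_ratios is not None:
            hr = self.cvd_hazard_ratios
            if len(hr) != 4 or any(x < 0 for x in hr):
                raise ParameterError("cvd_hazard_ratios must be 4 non-negative multipliers")
            if self.baseline_cvd_annual_rate is None:
                raise ParameterError(
                    "baseline_cvd_annual_rate is required when cvd_hazard_ratios are used "
                    "(no printed default exists; the shipped value is calibrated)")
            if self.baseline_cvd_annual_rate < 0:
                raise ParameterError("baseline_cvd_annual_rate must be >= 0")
        else:
            if self.framingham is None:
                raise ParameterError("either cvd_hazard_ratios or framingham assumptions must be provided")
            self.framingham.validate()
        if self.cvd_rate_scale < 0:
            raise ParameterError("cvd_rate_scale must be >= 0")
        if self.pppm_denominator not in ("enrolled_months", "active_months"):
            raise ParameterError(f"unknown pppm_denominator {self.pppm_denominator!r}")
        self.utilities.validate()
        self.delays.validate()
        self.attrition.validate()
        self.synthesis.validate()
        if self.transition_tables is not None:
            self.transition_tables.validate()
        return self

    # -- convenience --------------------------------------------------------
    def copy(self, **overrides) -> "ModelParameters":
        """Deep copy with optional field overrides (does not re-validate)."""
        new = _copy.deepcopy(self)
        for k, v in overrides.items():
            if not hasattr(new, k):
                raise ParameterError(f"unknown parameter field {k!r}")
            setattr(new, k, v)
        return new

    @property
    def diabetic_prevalence(self) -> float:
        """Diabetes prevalence used for the Framingham diabetic flag."""
        if self.disease.key == "t2dm":
            return 1.0
        return self.comorbidity_prevalence.get("t2dm", 0.0)

    # -- serialization ------------------------------------------------------
    def to_config(self) -> dict:
        def block(obj):
            return {k: (list(v) if isinstance(v, (tuple, np.ndarray)) else v)
                    for k, v in dataclasses.asdict(obj).items()}

        cfg: dict = {
            "disease": self.disease.key,
            "mean_age": self.mean_age,
            "enrollment_distribution": [float(x) for x in self.enrollment_distribution],
            "comorbidity_prevalence": dict(self.comorbidity_prevalence),
            "med_costs": {k: {"base_annual_cost": g.base_annual_cost, "slopes": list(g.slopes)}
                          for k, g in self.med_costs.items()},
            "cat2_unmedicated_fraction": self.cat2_unmedicated_fraction,
            "cvd_event_cost": self.cvd_event_cost,
            "utilities": block(self.utilities),
            "delays": block(self.delays),
            "attrition": block(self.attrition),
            "synthesis": block(self.synthesis),
            "discount_rate": self.discount_rate,
            "horizon_years": self.horizon_years,
            "tau_persistence": self.tau_persistence,
            "tau_spill_rule": self.tau_spill_rule,
            "cvd_rate_scale": self.cvd_rate_scale,
            "allow_synthesis": self.allow_synthesis,
            "pppm_denominator": self.pppm_denominator,
        }
        if self.cvd_hazard_ratios is not None:
            cfg["cvd_hazard_ratios"] = list(self.cvd_hazard_ratios)
            cfg["baseline_cvd_annual_rate"] = self.baseline_cvd_annual_rate
        if self.framingham is not None:
            cfg["framingham"] = block(self.framingham)
        if self.transition_tables is not None:
            t = self.transition_tables
            cfg["transition_tables"] = {
                "year1": np.asarray(t.year1).tolist(),
                "later": {int(y): np.asarray(M).tolist() for y, M in t.later.items()},
                "responder_fraction": t.responder_fraction,
                "mean_change": t.mean_change,
            }
        return cfg


# ---------------------------------------------------------------------------
# Base-case defaults
# ---------------------------------------------------------------------------

#: Calibrated placeholders for quantities the published tables do not print.
#: Values were solved once so that the base-case models reproduce the
#: published year-1/2/3 PPPM savings; they are inputs, not outputs, of every
#: run in this package.  See docs/methods.md ("Calibration").
CALIBRATED: dict[str, dict[str, float]] = {
    "t2dm": {
        "baseline_cvd_annual_rate": 0.0474273971961,
        "y2_improvement": 0.867718419454,
        "y3_improvement": 0.632187828473,
    },
    "htn": {
        "cvd_rate_scale": 1.95839964995,
        "y2_improvement": 0.244740614186,
        "y3_improvement": 0.135817896554,
    },
}


def default_parameters(disease: str | DiseaseSpec) -> ModelParameters:
    """Base-case parameter set for one disease model, exactly as printed,
    plus the documented calibrated placeholders.

    Transition tables are left unset; they are synthesized on first use
    (``allow_synthesis=True``) to satisfy the printed year-1 responder
    fraction and mean biomarker change.
    """
    d = get_disease(disease)
    cal = CALIBRATED[d.key]
    if d.key == "t2dm":
        p = ModelParameters(
            disease=d,
            mean_age=50.0,
            enrollment_distribution=np.array([0.0, 0.47, 0.34, 0.19]),
            comorbidity_prevalence={"hc": 0.60, "htn": 0.60},
            med_costs={
                "t2dm": CostGradient(2466.0, (0.0, 0.33, 1.2, 2.2)),
                "hc": CostGradient(775.0, (0.5, 0.8, 1.5, 2.0)),
                "htn": CostGradient(1557.0, (0.0, 0.15, 0.9, 1.8)),
            },
            cat2_unmedicated_fraction=0.25,
            cvd_event_cost=116423.0,
            cvd_hazard_ratios=(1.0, 1.0, 1.25, 1.98),
            baseline_cvd_annual_rate=cal["baseline_cvd_annual_rate"],
            utilities=UtilitySet(
                anchor_utility=0.82, cat1_increment=0.02, cat2_on_meds_increment=-0.02,
                cat3_increment=-0.035, cat4_increment=-0.025),
            delays=DelayParameters(),
            attrition=AttritionSchedule(),
            synthesis=SynthesisConstraints(
                responder_fraction_y1=0.62, mean_change_y1=-0.8,
                y2_improvement=cal["y2_improvement"], y3_improvement=cal["y3_improvement"]),
        )
    else:
        p = ModelParameters(
            disease=d,
            mean_age=50.0,
            enrollment_distribution=np.array([0.0, 0.37, 0.19, 0.44]),
            comorbidity_prevalence={"t2dm": 0.33},
            med_costs={
                "htn": CostGradient(1557.0, (0.0, 0.15, 0.9, 1.8)),
                "t2dm": CostGradient(2466.0, (0.0, 0.33, 1.2, 2.2)),
            },
            cat2_unmedicated_fraction=0.25,
            cvd_event_cost=116423.0,
            framingham=FraminghamAssumptions(),
            cvd_rate_scale=cal["cvd_rate_scale"],
            utilities=UtilitySet(
                anchor_utility=0.83, cat1_increment=0.025, cat2_on_meds_increment=-0.01,
                cat3_increment=-0.03, cat4_increment=0.0),
            delays=DelayParameters(),
            attrition=AttritionSchedule(),
            synthesis=SynthesisConstraints(
                responder_fraction_y1=0.87, mean_change_y1=-11.0,
                y2_improvement=cal["y2_improvement"], y3_improvement=cal["y3_improvement"]),
        )
    return p.validate()


# ---------------------------------------------------------------------------
# Sensitivity-analysis registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SAEntry:
    """One sensitivity-analysis row: how to read and perturb one parameter.

    ``kind='relative'`` interprets (low, high) as multiplicative offsets on the
    current base value (e.g. -0.20/+0.20); ``'absolute'`` as explicit bound
    values.  Tuple-valued parameters (gradients, hazard ratios) are scaled
    element-wise by one common factor, mirroring the single printed range per
    table row.
    """

    name: str
    units: str
    kind: str                 # "relative" | "absolute"
    low: float
    high: float
    getter: callable
    setter: callable
    printed_form: str = ""
    resynthesize: bool = False   # perturbation invalidates transition tables

    def bound_value(self, params: ModelParameters, direction: str) -> float:
        if direction not in ("low", "high"):
            raise ParameterError(f"direction must be 'low' or 'high', got {direction!r}")
        off = self.low if direction == "low" else self.high
        base = self.getter(params)
        return base * (1.0 + off) if self.kind == "relative" else off


def _med_cost_entry(drug: str, printed: str) -> SAEntry:
    return SAEntry(
        name=f"{drug}_med_cost", units="USD/year", kind="relative", low=-0.20, high=0.20,
        getter=lambda p: p.med_costs[drug].base_annual_cost,
        setter=lambda p, v: setattr(p.med_costs[drug], "base_annual_cost", v),
        printed_form=printed)


def _gradient_entry(drug: str) -> SAEntry:
    def get(p):
        return 1.0  # scale factor relative to current slopes

    def set_(p, v):
        p.med_costs[drug] = CostGradient(
            p.med_costs[drug].base_annual_cost,
            tuple(s * v for s in p.med_costs[drug].slopes))

    return SAEntry(name=f"{drug}_med_gradient", units="scale", kind="relative",
                   low=-0.10, high=0.10, getter=get, setter=set_, printed_form="±10%")


def _utility_entry(field_name: str) -> SAEntry:
    return SAEntry(
        name=f"utility_{field_name}", units="utility", kind="relative", low=-0.20, high=0.20,
        getter=lambda p: getattr(p.utilities, field_name),
        setter=lambda p, v: setattr(p.utilities, field_name, v),
        printed_form="±20%")


def sa_registry(params: ModelParameters) -> list[SAEntry]:
    """Every one-way SA parameter for the given disease model, in table order."""
    d = params.disease.key
    entries: list[SAEntry] = [
        SAEntry("mean_age", "years", "absolute",
                params.mean_age - 5.0, params.mean_age + 5.0,
                lambda p: p.mean_age, lambda p, v: setattr(p, "mean_age", v), "±5"),
    ]

    def comorbid(name, low, high, printed):
        return SAEntry(
            f"comorbid_{name}_prevalence", "fraction", "relative", low, high,
            getter=lambda p: p.comorbidity_prevalence[name],
            setter=lambda p, v: p.comorbidity_prevalence.__setitem__(name, v),
            printed_form=printed)

    if d == "t2dm":
        entries += [comorbid("hc", -0.30, 0.10, "+10/-30"),
                    comorbid("htn", -0.30, 0.10, "+10/-30")]
    else:
        entries += [comorbid("t2dm", -0.20, 0.20, "±20%")]

    entries += [
        SAEntry("dtx_responder_fraction", "fraction", "relative", -0.33, 0.10,
                lambda p: p.synthesis.responder_fraction_y1,
                lambda p, v: setattr(p.synthesis, "responder_fraction_y1", v),
                "+10/-33", resynthesize=True),
        SAEntry("dtx_mean_improvement", params.disease.units, "relative", -0.40, 0.20,
                lambda p: p.synthesis.mean_change_y1,
                lambda p, v: setattr(p.synthesis, "mean_change_y1", v),
                "+20/-40", resynthesize=True),
        SAEntry("cat2_unmedicated_fraction", "fraction", "absolute", 0.0, 0.50,
                lambda p: p.cat2_unmedicated_fraction,
                lambda p, v: setattr(p, "cat2_unmedicated_fraction", v), "25 (0/50)"),
    ]

    if d == "t2dm":
        entries += [_med_cost_entry("t2dm", "2466 ±20%"),
                    _med_cost_entry("hc", "775 ±20%"),
                    _med_cost_entry("htn", "1557 ±20%"),
                    _gradient_entry("t2dm"), _gradient_entry("hc"), _gradient_entry("htn")]
    else:
        entries += [_med_cost_entry("htn", "1557 ±20%"),
                    _med_cost_entry("t2dm", "2466 ±20%"),
                    _gradient_entry("htn"), _gradient_entry("t2dm")]

    entries += [
        SAEntry("cvd_event_cost", "USD", "relative", -0.20, 0.20,
                lambda p: p.cvd_event_cost,
                lambda p, v: setattr(p, "cvd_event_cost", v), "116423 ±20%"),
    ]
    if d == "t2dm":
        def set_hr(p, v):
            p.cvd_hazard_ratios = tuple(h * v for h in p.cvd_hazard_ratios)

        entries += [SAEntry("cvd_hazard_ratios", "scale", "relative", -0.10, 0.10,
                            lambda p: 1.0, set_hr, "1/1/1.25/1.98 ±10%")]

    entries += [_utility_entry("cat1_increment"), _utility_entry("cat2_on_meds_increment"),
                _utility_entry("cat3_increment")]
    if params.utilities.cat4_increment != 0.0:
        entries += [_utility_entry("cat4_increment")]
    entries += [
        _utility_entry("cvd_event_increment"),
        SAEntry("medication_delay_months", "months", "absolute",
                params.delays.medication_delay_months - 3.0,
                params.delays.medication_delay_months + 3.0,
                lambda p: p.delays.medication_delay_months,
                lambda p, v: setattr(p.delays, "medication_delay_months", v), "6 ±3"),
        SAEntry("cvd_delay_months", "months", "absolute",
                params.delays.cvd_delay_months - 1.0,
                params.delays.cvd_delay_months + 1.0,
                lambda p: p.delays.cvd_delay_months,
                lambda p, v: setattr(p.delays, "cvd_delay_months", v), "3 ±1"),
        SAEntry("discount_rate", "fraction/year", "absolute", 0.0, 0.05,
                lambda p: p.discount_rate,
                lambda p, v: setattr(p, "discount_rate", v), "3 (0/5)"),
    ]
    return entries


def apply_sa_bound(params: ModelParameters, parameter_name: str, direction: str) -> ModelParameters:
    """Copy of ``params`` with one parameter moved to its SA bound.

    Asymmetric printed ranges are honored (effectiveness +20/-40, responder
    +10/-33, comorbidity +10/-30, category-2 unmedicated 0/50).  Perturbing an
    effectiveness parameter drops any synthesized transition tables so they
    are regenerated under the new constraints.
    """
    entries = {e.name: e for e in sa_registry(params)}
    if parameter_name not in entries:
        raise ParameterError(
            f"no sensitivity range declared for {parameter_name!r}; "
            f"known: {sorted(entries)}")
    entry = entries[parameter_name]
    out = params.copy()
    entry.setter(out, entry.bound_value(params, direction))
    if entry.resynthesize:
        out.transition_tables = None
        # the responder-fraction and mean-change constraints are perturbed
        # independently (one printed range per row); if a bound makes the
        # pair jointly unreachable by the table ansatz, re-target the mean
        # change to the nearest achievable value -- loudly
        from .synthesis import achievable_mean_range

        strongest, weakest = achievable_mean_range(out)
        m = out.synthesis.mean_change_y1
        clamped = min(max(m, strongest), weakest)
        if clamped != m:
            logger.warning(
                "SA bound %s=%s makes mean change %g unreachable "
                "(achievable [%g, %g]); re-targeted to %g",
                parameter_name, direction, m, strongest, weakest, clamped)
            out.synthesis.mean_change_y1 = clamped
    return out.validate()


def registry_frame(params: ModelParameters):
    """Parameter registry as a DataFrame: (name, base_value, sa_low, sa_high,
    units, printed_form)."""
    import pandas as pd

    rows = []
    for e in sa_registry(params):
        rows.append({
            "name": e.name,
            "base_value": e.getter(params),
            "sa_low": e.bound_value(params, "low"),
            "sa_high": e.bound_value(params, "high"),
            "units": e.units,
            "printed_form": e.printed_form,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

_BLOCK_TYPES = {
    "utilities": UtilitySet,
    "delays": DelayParameters,
    "attrition": AttritionSchedule,
    "synthesis": SynthesisConstraints,
    "framingham": FraminghamAssumptions,
}


def serialize_parameters(params: ModelParameters) -> str:
    """YAML rendering of the full parameter set (lossless round-trip)."""
    return yaml.safe_dump(params.to_config(), sort_keys=False, default_flow_style=None)


def load_parameters(config_source) -> ModelParameters:
    """Build validated ``ModelParameters`` from YAML text, a path, a file
    object, or an already-parsed mapping.

    Keys absent from the config fall back to the disease base case, with a
    logged notice.  Invariant violations raise :class:`ParameterError` naming
    the offending field.
    """
    if isinstance(config_source, dict):
        cfg = _copy.deepcopy(config_source)
    elif isinstance(config_source, io.IOBase):
        cfg = yaml.safe_load(config_source.read())
    else:
        text = str(config_source)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text) as fh:
                cfg = yaml.safe_load(fh)
        else:
            cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ParameterError("config must parse to a mapping")
    if "disease" not in cfg:
        raise ParameterError("config is missing required key 'disease'")

    params = default_parameters(cfg.pop("disease"))
    base_cfg = params.to_config()
    base_cfg.pop("disease")

    for key, value in cfg.items():
        if key == "transition_tables":
            params.transition_tables = _table_from_config(value)
            continue
        if key not in base_cfg and key not in ("cvd_hazard_ratios", "baseline_cvd_annual_rate", "framingham"):
            raise ParameterError(f"unknown config key {key!r}")
        if key in _BLOCK_TYPES and isinstance(value, dict):
            block = getattr(params, key) or _BLOCK_TYPES[key]()
            for sub, v in value.items():
                if not hasattr(block, sub):
                    raise ParameterError(f"unknown config key {key}.{sub}")
                setattr(block, sub, v)
            setattr(params, key, block)
        elif key == "med_costs":
            for drug, entry in value.items():
                params.med_costs[drug] = CostGradient(
                    float(entry["base_annual_cost"]), tuple(entry["slopes"]))
        elif key == "comorbidity_prevalence":
            params.comorbidity_prevalence.update(value)
        elif key == "enrollment_distribution":
            params.enrollment_distribution = np.asarray(value, dtype=float)
        elif key == "cvd_hazard_ratios":
            params.cvd_hazard_ratios = tuple(value)
        else:
            setattr(params, key, value)

    unspecified = [k for k in base_cfg if k not in cfg]
    if unspecified:
        logger.info("config for %s: %d keys fall back to base case (%s)",
                    params.disease.key, len(unspecified), ", ".join(sorted(unspecified)[:6]) + "...")
    return params.validate()


def _table_from_config(value: dict) -> TransitionTable:
    t = TransitionTable(
        year1=np.asarray(value["year1"], dtype=float),
        later={int(y): np.asarray(M, dtype=float) for y, M in value["later"].items()},
        responder_fraction=value.get("responder_fraction"),
        mean_change=value.get("mean_change"),
    )
    t.validate()
    return t


def parameters_equal(a: ModelParameters, b: ModelParameters, tol: float = 0.0) -> bool:
    """Field-wise equality via the config representation (arrays compared
    exactly, or within ``tol`` if given)."""
    def flatten(d, prefix=""):
        for k, v in sorted(d.items()):
            if isinstance(v, dict):
                yield from flatten(v, f"{prefix}{k}.")
            else:
                yield f"{prefix}{k}", v

    fa, fb = dict(flatten(a.to_config())), dict(flatten(b.to_config()))
    if fa.keys() != fb.keys():
        return False
    for k, va in fa.items():
        vb = fb[k]
        if isinstance(va, (int, float)) and isinstance(vb, (int, float)):
            if abs(float(va) - float(vb)) > tol:
                return False
        elif isinstance(va, list):
            if not np.allclose(np.asarray(va, dtype=float), np.asarray(vb, dtype=float), atol=tol):
                return False
        elif va != vb:
            return False
    return True
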