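# Methods

`dtxecon` implements two deterministic decision-analytic cohort models
estimating, from a US commercial-payer perspective, the health-resource-use
(HRU) savings and cost effectiveness of adding a digital therapeutic (DTx) to
treatment as usual (TAU) in type 2 diabetes (T2DM) and hypertension (HTN)
over a 3-year horizon.

## Model structure

Patients enroll at the start of year 1 with active disease and are classified
into four outcome categories on the disease biomarker:

| category | T2DM (HbA1c, %) | HTN (SBP, mm Hg) |
|---|---|---|
| 1 | < 6.5 | < 120 |
| 2 | 6.5 – 7.49 | 120 – 129 |
| 3 | 7.5 – 9.0 (inclusive) | 130 – 139 |
| 4 | > 9.0 | ≥ 140 |

Category boundaries are left-closed on the printed lower bound; HbA1c 9.0
belongs to category 3 (the category is worded "7.5% to 9.0%"). No category-1
patients enroll. Enrollment distributions: T2DM (0, 0.47, 0.34, 0.19), HTN
(0, 0.37, 0.19, 0.44).

Two arms are compared. **TAU alone** keeps full mass and is stable: each year
80% of patients remain in their *enrollment* category and the remaining 20%
spills symmetrically to adjacent categories (reflecting inward at the ends).
The spill rule is a modeling choice — the source material specifies only the
80% persistence — and is configurable (`tau_spill_rule`). Because the
transition is re-applied to the enrollment distribution each year rather than
iterated, the TAU arm is stationary, matching the description of TAU outcomes
as "relatively stable."

**DTx + TAU** evolves through year-specific transition tables, *stratified by
enrollment category* so that the assumption that category-4 enrollees are
more resistant to later improvement can be carried through years 2–3.

## Program attrition

20% of enrollees withdraw at month 3 of year 1 (no engagement / no early
improvement), a further 20% of the remainder at year-1 end (improvement not
durable), and 10% of the remaining actives during each of years 2 and 3
(mid-year), leaving 64%, 57.6% and 51.84% active at the ends of years 1–3;
36% withdraw within year 1. Return rules:

* Month-3 withdrawers carry their enrollment values all of year 1 (no
  improvement had occurred).
* Year-end withdrawers accrue active-arm (delay-gated) membership during
  year 1 and revert to enrollment values at year end.
* Year-2/3 withdrawers spend half the withdrawal year at the previous
  year-end active distribution and half at the TAU average, joining the TAU
  pool thereafter. Mid-year timing is a convention (the source gives none);
  it is configurable (`attrition.y23_month`).
* All past withdrawers are costed at the year's TAU average distribution in
  subsequent years (year-1 withdrawers return *to enrollment*, which is also
  where TAU-alone patients are anchored; treating them as ordinary TAU
  patients thereafter keeps the arms commensurable).

Attrition is from the DTx program, not the health plan: both arms retain full
mass for costing throughout.

## Transition-table synthesis

The year-by-year decision trees behind the published model are in a
supplementary appendix that is not distributed with the main text, so the
package synthesizes tables from the printed constraints (a transcribed table
in the CSV/YAML dialect is used verbatim when supplied):

* year-1 responder fraction (patients improving ≥ 1 category): 0.62 (T2DM),
  0.87 (HTN);
* year-1 mean biomarker change among those remaining: −0.8% HbA1c, −11 mm Hg
  SBP.

Ansatz: in each enrolled category a fraction *r* of patients improves exactly
one category; one scalar degree of freedom then matches the mean change,
computed with category-midpoint representative biomarker values: either a
fraction of category-3/4 responders jumps two (then three) categories, or a
fraction of non-responders worsens one category. The implied mean change is
monotone in this parameter, so the solution is unique; targets outside the
achievable interval raise an explicit infeasibility error with the achievable
range. Representative values use outer-bin caps HbA1c 5.5–12% and SBP
110–160 mm Hg. The SBP category-4 representative (150 mm Hg, a typical
stage-2 cohort mean) is deliberately below the bin midpoint of wider caps:
with a higher value the two printed year-1 constraints are jointly
unsatisfiable by any category-move table.

Years 2–3 apply "small incremental improvement" rows: each active patient
improves one category with probability `y2_improvement` / `y3_improvement`,
halved (`category4_damping = 0.5`) for the enrolled-category-4 stratum.

## Costs

Annual medication cost in category *k* is `base × slope[k]` with printed
bases/slopes (T2DM $2,466 × 0/0.33/1.2/2.2; high cholesterol $775 ×
0.5/0.8/1.5/2; HTN $1,557 × 0/0.15/0.9/1.8). A patient's primary-disease
category also indexes the comorbidity gradients (prevalences: T2DM model —
HC 60%, HTN 60%; HTN model — T2DM 33%), the only coupling the printed
gradients support. 25% of category-2 patients in the DTx arm are managed
without primary-disease medications (`cat2_unmedicated_fraction`); TAU
category-2 patients are all medicated.

CVD inpatient events cost $116,423 each and accrue as expected values:

* **T2DM**: annual rate = baseline rate × hazard ratio by category
  (1/1/1.25/1.98). The baseline rate is not printed anywhere in the main
  text; it ships as a **calibrated placeholder** (0.0474/person-year, see
  Calibration).
* **HTN**: per-category 10-year Framingham general-CVD risk at the category's
  representative SBP — mixed over sex (50/50), smoking (14%, the US adult
  rate), comorbid diabetes (33%), and treatment status (categories with a
  zero medication slope, and the DTx-arm unmedicated category-2 share, use
  the untreated-SBP coefficient) — converted to an annual probability under a
  constant hazard and multiplied by a **calibrated payer scale** (1.958).
  The scale absorbs the unprinted mapping from general-CVD risk (which
  includes events beyond payer-borne hospitalizations, for an epidemiological
  cohort rather than a treated claims population) to hospitalization cost.
  Cholesterol (TC 200, HDL 50 mg/dL) and smoking inputs are documented
  assumptions exposed in config. The Framingham coefficients are transcribed
  from the primary-care general-CVD risk publication and verified in the test
  suite against that publication's worked example.

**Clinical inertia.** Economic benefits in year 1 are delayed: medications
are reduced only after 6 months of sustained improvement, CVD risk reduction
begins after 3 months. Year-1 active-stratum costs are a within-year blend:
`(delay/12)` of the year at the enrollment distribution under TAU medication
status, the rest at the year-1-end distribution under DTx status — the
pre-improvement baseline is the enrollment state, which is where a DTx
patient sits before the program takes effect. Years 2–3 are not delayed.
`apply_benefit_delay` exposes the equivalent savings-side proration
(`saving × (12 − delay)/12` in year 1).

Future costs and QALYs are discounted at 3%/year with year 1 as the present
(`value/(1+r)^(y−1)`). Costs are 2018 dollars; no further adjustment.

**PPPM savings** (per participant per month) divide each year's undiscounted
arm difference by enrolled person-months (`enrolled_n × 12`), i.e. "per
enrollee per month in year-1 dollars". An `active_months` alternative
(program person-months in the denominator) is available in config; see
Limitations for why the two conventions tell different stories about the
year-2/3 improvement magnitudes.

## Utilities and QALYs

Utilities anchor at category 2 without medications (0.82 T2DM, 0.83 HTN) with
printed increments: category 1 +0.02/+0.025, category 2 on medications
−0.02/−0.01, category 3 −0.035/−0.03, category 4 −0.025/0, CVD event −0.1 in
the event year (expected-value treatment, rate × decrement; no recurrence or
mortality). The default `increment_mode="absolute"` applies each increment to
the anchor exactly as printed — including the HTN category-4 increment of 0
and the resulting non-monotone T2DM category-4 value (0.795 > category 3's
0.785). A `cumulative` mode chains the increments
(cat3 = cat2-on-meds + inc3, cat4 = cat3 + inc4) and restores monotonicity.
Absolute mode is the default both because it is the printed arithmetic and
because the implied T2DM QALY gain (0.0394/enrollee) sits next to the slope
of the published threshold curves ((8348 − 6468)/50 000 = 0.0376), which the
cumulative mode (0.056) does not.

QALY accrual mirrors cost accrual segment by segment, including the year-1
delay blend (a deprescribed category-2 patient gains the no-medication
utility only after the 6-month delay). No half-cycle correction beyond the
stated delays.

## Cost effectiveness

Per enrollee, `Δsavings` is the discounted 3-year HRU saving and `ΔQALY` the
discounted QALY gain. With the 3-year program cost `C` treated as an upfront
total (a flag to spread-and-discount was considered and rejected as the less
parsimonious reading), the intervention is cost effective at willingness-to-
pay λ iff `C ≤ breakeven(λ) = Δsavings + λ·ΔQALY` — affine in λ with slope
`ΔQALY` by construction, which the tests verify to machine precision.

## Sensitivity analysis

Every printed parameter range is a one-way entry: two full model runs at the
bounds, all else at base, tornado-sorted by outcome span. Asymmetric ranges
are honored: DTx mean improvement +20/−40%, responder fraction +10/−33%,
comorbidity prevalence +10/−30 (T2DM model), category-2 unmedicated share
0–50 (absolute), delays ±3 and ±1 months, discount 0–5%. Tuple-valued rows
(gradients, hazard ratios, ±10%) scale all elements by one factor, mirroring
the single printed range per row. The responder fraction and mean change are
perturbed independently (they are separate printed rows); if a bound makes
the pair jointly unreachable by the table ansatz — the HTN responder high
bound does — the mean-change constraint is re-targeted to the nearest
achievable value with a logged warning.

Enrollment severity is handled as discrete scenarios rather than a ±%
perturbation (a distribution cannot be scaled and remain a distribution):
`severity_34_only` / `severity_4_only` re-weight enrollment over categories
3–4 / 4, *keeping the base-case transition tables* — the intervention's
per-category effect does not depend on who enrolls, and re-synthesizing
against a severity-restricted cohort would change the intervention itself.

## Calibration

Four quantities the printed tables do not contain are required to close the
model. They were solved once — by root-finding against the published yearly
PPPM savings (83/174/178 T2DM; 70/113/107 HTN) under the base case — and are
shipped as frozen, documented constants (`parameters.CALIBRATED`); every run
treats them as inputs:

| quantity | T2DM | HTN |
|---|---|---|
| baseline CVD annual rate (events/person-yr) | 0.04743 | — |
| Framingham payer scale | — | 1.9584 |
| year-2 improvement probability | 0.8677 | 0.2447 |
| year-3 improvement probability | 0.6322 | 0.1358 |

The year-1 values pin the CVD quantities (year 1 is independent of the
later-year improvements), then years 2 and 3 pin the improvement
probabilities sequentially.

## Synthetic data and the microsimulation oracle

`random_parameter_set` draws every sensitivity-analysis parameter uniformly
within its range (rejecting the rare draws whose effectiveness pair is
infeasible for the table ansatz) for property tests. `microsimulate` samples
individual patients — enrollment category, withdrawal times, category paths —
under exactly the engine's rules, accumulating costs and QALYs as conditional
expectations given the sampled path (rates rather than sampled events:
unbiased for the cohort mean, lower variance). The test suite requires
agreement with the deterministic engine within 3 standard errors at n = 10⁵
on 20 seeded random parameter sets. The generator emulates the *model's* own
stochastic reading of itself; it does not emulate features of real claims
data (seasonality, censoring, cost skewness, correlated comorbidity), so
passing tests validate internal consistency, not real-world performance.

## Numerical choices

* Transition rows validated stochastic to 1e-9; synthesis residuals: exact
  responder fraction, mean change within 1e-6, root solved to 1e-13.
* All pipeline stages are pure NumPy linear algebra; re-runs are
  bit-identical. Randomness exists only in `random_parameter_set` and
  `microsimulate`, both seeded through `numpy.random.default_rng`.
* Degenerate inputs: zero attrition, zero responders (identity tables),
  persistence 1, discount 0, and empty comorbidity maps are all exercised in
  tests.

## Known limitations

* The supplementary transition trees being unavailable, all year-2/3 dynamics
  rest on the one-parameter improvement ansatz plus calibration. Under the
  default enrolled-person-month PPPM denominator, reproducing the published
  year-2/3 savings needs large improvement probabilities (0.87/0.63 in T2DM)
  — in tension with the stated "small improvements" in years 2–3. Under the
  `active_months` denominator the calibrated probabilities are genuinely
  small (~0.12/0.05) but the implied discounted savings fall well below the
  published threshold curves. The default follows the "per enrollee per
  month" caption; both conventions are exposed.
* The published break-even program costs are not jointly reproducible with
  the published PPPM savings under any setting here: the printed pairs imply
  a discounted-savings intercept (~$4,588 T2DM) below what the printed PPPM
  values integrate to at 3% ($5,037), and the HTN pair implies a QALY gain
  (~0.072/enrollee) several times larger than the printed utility increments
  can generate. The package reports its own internally consistent values.
* The published delay sensitivity for T2DM year 1 ($55/$98 around $83) is
  asymmetric; linear within-year proration is symmetric and reproduces the
  long-delay bound ($55) but not the short-delay one (model: $111).
* With the large calibrated T2DM improvement probabilities, the
  category-4-only scenario is not strictly below the categories-3+4 scenario
  in years 2–3 (it is in HTN); the enrollment-stratified damping carries the
  intended direction but not the full published contrast.
* No CVD mortality, no adverse-event costs, no health-plan turnover, no
  probabilistic sensitivity analysis — all outside this model family's scope.
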