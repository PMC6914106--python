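# dtxecon

Decision-analytic cohort models of the health-economic impact of **digital
therapeutics (DTx)** — software-delivered behavioral interventions — added to
pharmacologic treatment as usual (TAU) in **type 2 diabetes** and
**hypertension**, from a US commercial-payer perspective over a 3-year
horizon.

The package is for health-economics analysts who want to reproduce, stress,
or extend this class of budget-impact / cost-utility model: it exposes every
parameter (with its one-way sensitivity range) in config, a deterministic
cohort engine, an individual-level microsimulation that serves as a
brute-force cross-check, and report writers for the standard outputs.

## The model in brief

Patients enroll in one of four biomarker categories (HbA1c bins for diabetes,
systolic-blood-pressure bins for hypertension). Two cohorts are compared:
DTx + TAU, which moves patients toward better categories through year-by-year
transition tables with program attrition (20% at month 3, 20% more at year-1
end, 10% in each later year), and TAU alone, in which 80% of patients stay in
their enrollment category. Category occupancy drives

* medication costs via printed cost gradients (annual base cost × category
  slope, for the primary disease and prevalence-weighted comorbidities),
* cardiovascular inpatient costs via hazard ratios by HbA1c level (diabetes)
  or the Framingham 10-year general-CVD risk equation (hypertension),
* health-state utilities anchored at category 2 without medications.

**Clinical inertia** delays the economic benefit of improvement: medications
are deprescribed only after 6 months of sustained improvement, CVD risk falls
after 3 months. Yearly savings are reported per participant per month
(PPPM); cost effectiveness as the **break-even 3-year program cost**
`breakeven(λ) = ΔHRU savings + λ·ΔQALY` at willingness-to-pay λ — the
net-monetary-benefit threshold line.

Quantities the published tables do not print (the baseline CVD event rate
behind the diabetes hazard ratios, the payer scale on Framingham risk, and
the year-2/3 incremental-improvement probabilities) ship as documented
**calibrated constants**; `docs/methods.md` describes the model, the
transition-table synthesis, and the calibration in full.

## Worked example

```sh
dtxecon run --disease t2dm --out results/
```

prints

```
Type 2 diabetes mellitus (HbA1c, %) - DTx + TAU vs TAU alone
HRU savings per participant per month (year-1 dollars):
  year 1: $83
  year 2: $174
  year 3: $178
  3-year average: $145
Discounted 3-year HRU savings per enrollee: $5,037
Incremental QALYs per enrollee: 0.0394
Break-even 3-year program cost at $50k/QALY: $7,008
Break-even 3-year program cost at $100k/QALY: $8,979
```

Year-1 savings are lower than later years because of the clinical-inertia
delays; the 3-year average means a diabetes DTx that displaces medication use
saves the payer about $145 per enrollee-month in health-resource use, before
program costs. The break-even figures say such a program is cost effective at
$50,000/QALY as long as its total 3-year cost stays under about $7,000 per
enrollee. The same library calls are available in Python:

```python
import dtxecon as dx

params = dx.default_parameters("htn")        # or dx.load_parameters("my.yaml")
run = dx.run_model(params)
run.pppm                                     # array([ 70., 113., 107.])
run.cea.breakeven(50_000)                    # 4065.0
```

Other subcommands: `dtxecon sa` (one-way tornado sensitivity over every
parameter range), `dtxecon scenario --name severity_34_only` (enrollment
restricted to the two most severe categories; raises average savings ×1.51
in diabetes), `dtxecon simulate` (microsimulation cross-check), and
`dtxecon threshold` (the full break-even curve). Base-case configs for both
diseases are under `configs/`; any subset of keys may be overridden.

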