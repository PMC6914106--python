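# Base-case parameters for the t2dm model.
# Every key is optional in user configs; omitted keys fall back to these values.
disease: t2dm
mean_age: 50.0
enrollment_distribution: [0.0, 0.47, 0.34, 0.19]
comorbidity_prevalence: {hc: 0.6, htn: 0.6}
med_costs:
  t2dm:
    base_annual_cost: 2466.0
    slopes: [0.0, 0.33, 1.2, 2.2]
  hc:
    base_annual_cost: 775.0
    slopes: [0.5, 0.8, 1.5, 2.0]
  htn:
    base_annual_cost: 1557.0
    slopes: [0.0, 0.15, 0.9, 1.8]
cat2_unmedicated_fraction: 0.25
cvd_event_cost: 116423.0
utilities: {anchor_utility: 0.82, cat1_increment: 0.02, cat2_on_meds_increment: -0.02,
  cat3_increment: -0.035, cat4_increment: -0.025, cvd_event_increment: -0.1, increment_mode: absolute}
delays: {medication_delay_months: 6.0, cvd_delay_months: 3.0}
attrition: {y1_early: 0.2, y1_late: 0.2, y2: 0.1, y3: 0.1, y1_early_month: 3.0, y23_month: 6.0,
  y1_return_rule: to_enrollment, y23_return_rule: to_tau_average}
synthesis: {responder_fraction_y1: 0.62, mean_change_y1: -0.8, y2_improvement: 0.867718419454,
  y3_improvement: 0.632187828473, category4_damping: 0.5, two_category_fraction: null}
discount_rate: 0.03
horizon_years: 3
tau_persistence: 0.8
tau_spill_rule: symmetric_adjacent
cvd_rate_scale: 1.0
allow_synthesis: true
pppm_denominator: enrolled_months
cvd_hazard_ratios: [1.0, 1.0, 1.25, 1.98]
baseline_cvd_annual_rate: 0.0474273971961
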