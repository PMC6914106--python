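# Base-case parameters for the htn model.
# Every key is optional in user configs; omitted keys fall back to these values.
disease: htn
mean_age: 50.0
enrollment_distribution: [0.0, 0.37, 0.19, 0.44]
comorbidity_prevalence: {t2dm: 0.33}
med_costs:
  htn:
    base_annual_cost: 1557.0
    slopes: [0.0, 0.15, 0.9, 1.8]
  t2dm:
    base_annual_cost: 2466.0
    slopes: [0.0, 0.33, 1.2, 2.2]
cat2_unmedicated_fraction: 0.25
cvd_event_cost: 116423.0
utilities: {anchor_utility: 0.83, cat1_increment: 0.025, cat2_on_meds_increment: -0.01,
  cat3_increment: -0.03, cat4_increment: 0.0, cvd_event_increment: -0.1, increment_mode: absolute}
delays: {medication_delay_months: 6.0, cvd_delay_months: 3.0}
attrition: {y1_early: 0.2, y1_late: 0.2, y2: 0.1, y3: 0.1, y1_early_month: 3.0, y23_month: 6.0,
  y1_return_rule: to_enrollment, y23_return_rule: to_tau_average}
synthesis: {responder_fraction_y1: 0.87, mean_change_y1: -11.0, y2_improvement: 0.244740614186,
  y3_improvement: 0.135817896554, category4_damping: 0.5, two_category_fraction: null}
discount_rate: 0.03
horizon_years: 3
tau_persistence: 0.8
tau_spill_rule: symmetric_adjacent
cvd_rate_scale: 1.95839964995
allow_synthesis: true
pppm_denominator: enrolled_months
framingham: {total_cholesterol: 200.0, hdl_cholesterol: 50.0, smoking_prevalence: 0.14,
  female_fraction: 0.5}
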