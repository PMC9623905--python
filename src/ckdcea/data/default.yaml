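# Default model configuration: intensive vs. standard hypertension control in
# hypertensive CKD patients aged 50+.
#
# Age-dependent inputs are published only as (low, high) ranges over the
# cohort's age span; this pinned default expands them deterministically:
#   form: linear   — low at start_age rising linearly to high at max_age
#   form: midpoint — constant at the range mean
# Probabilities are annual; costs are USD per person per year (1,180 KRW/USD);
# utilities are QALY weights per year.

model:
  competing_risk_method: rate_based
  sae_persistent: false

economics:
  discount_rate: 0.05
  wtp_threshold: 31362.80       # 2019 Korean GDP per capita, USD/QALY
  krw_per_usd: 1180.0
  cycle_length: 1.0
  start_age: 50
  max_age: 100
  cohort_size: 72429
  half_cycle_correction: false

age_curves:
  incidence:
    mi:                      {range: [0.0, 0.0082], form: linear}
    stroke:                  {range: [0.0247, 0.0604], form: linear}
    hf:                      {range: [0.0247, 0.1275], form: linear}
    hypotension:             {range: [0.0, 0.0083], form: linear}
    syncope:                 {range: [0.0, 0.0201], form: linear}
    bradycardia:             {range: [0.0, 0.0132], form: linear}
    electrolyte_abnormality: {range: [0.0201, 0.0331], form: linear}
    injurious_fall:          {range: [0.3423, 0.3786], form: linear}
    acute_renal_failure:     {range: [0.0041, 0.0470], form: linear}
  mortality:
    hypertension:            {range: [0.0004, 0.0053], form: linear}
    mi:                      {range: [0.0, 0.0], form: linear}       # printed as 0%
    stroke:                  {range: [0.0, 0.0067], form: linear}
    hf:                      {range: [0.0, 0.0201], form: linear}
    hypotension:             {range: [0.0, 0.0041], form: linear}
    syncope:                 {range: [0.0, 0.0028], form: linear}
    bradycardia:             {range: [0.0, 0.0], form: linear}       # printed as 0%
    electrolyte_abnormality: {range: [0.0, 0.0026], form: linear}
    injurious_fall:          {range: [0.0041, 0.0134], form: linear}
    acute_renal_failure:     {range: [0.0, 0.0201], form: linear}
  costs:
    hypertension:            {range: [386.4, 1943.3], form: midpoint}
    mi:                      {range: [159.8, 26696.9], form: midpoint}
    stroke:                  {range: [2406.1, 14109.8], form: midpoint}
    hf:                      {range: [4508.8, 6371.5], form: midpoint}
    hypotension:             {range: [67.0, 7930.4], form: midpoint}
    syncope:                 {range: [494.6, 2882.2], form: midpoint}
    bradycardia:             {range: [365.0, 3643.9], form: midpoint}
    electrolyte_abnormality: {range: [643.6, 5511.5], form: midpoint}
    injurious_fall:          {range: [4157.2, 14087.9], form: midpoint}
    acute_renal_failure:     {range: [5418.7, 27676.9], form: midpoint}

utilities:
  hypertension: 1.00
  stroke: 0.65
  mi: 0.70
  hf: 0.64
  sae: 0.60

# Intensive-vs-standard hazard ratios with 95% CIs. disease_events is the
# published aggregate; the model applies the per-event ratios below it.
hazard_ratios:
  disease_events:          {point: 0.94, ci: [0.62, 1.44]}
  mi:                      {point: 1.35, ci: [0.60, 3.08]}
  stroke:                  {point: 0.99, ci: [0.57, 1.70]}
  hf:                      {point: 0.72, ci: [0.47, 1.10]}
  hypotension:             {point: 1.34, ci: [0.88, 2.04]}
  syncope:                 {point: 1.28, ci: [0.86, 1.92]}
  bradycardia:             {point: 0.92, ci: [0.59, 1.44]}
  electrolyte_abnormality: {point: 1.35, ci: [0.94, 1.94]}
  injurious_fall:          {point: 0.90, ci: [0.71, 1.15]}
  acute_renal_failure:     {point: 1.46, ci: [1.10, 1.95]}
  cvd_death:               {point: 0.57, ci: [0.31, 1.02]}
  non_cvd_death:           {point: 0.72, ci: [0.53, 0.99]}

strategies:
  standard:
    healthy_cost_multiplier: 1.0
    apply_hazard_ratios: false
  intensive:
    healthy_cost_multiplier: 1.2      # extra outpatient cost of tight control
    apply_hazard_ratios: true
    hr_application: rate_transform
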