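cohort_id: airwave
display_name: Airwave Health Monitoring Study
currency: GBP
rules:
  cohort_id:
    kind: identity
    source: cohort_id
  assessment_date:
    kind: date_truncate
    source: assessment_date
    dialect: iso
  date_of_birth:
    kind: date_truncate
    source: date_of_birth
    dialect: iso
  dna_extracted:
    kind: identity
    source: dna_extracted
  plasma_collected:
    kind: identity
    source: plasma_collected
  serum_collected:
    kind: identity
    source: serum_collected
  age:
    kind: identity
    source: age
  gender:
    kind: recode
    source: sex
    map:
      male: 1
      female: 2
  ethnicity:
    kind: recode
    source: ethnic_group
    map:
      White: 1
      Black: 2
      Asian: 3
      Mixed: 4
      Other: 5
  cohabitation:
    kind: recode
    source: marital_status
    map:
      Single: 1
      Married: 2
      Divorced: 3
      Separated: 3
      Widowed: 4
      Other: 5
  educational_level:
    kind: recode
    source: highest_qualification
    map:
      Post grad: 1
      Deg. equiv: 2
      A level NVQ3: 3
      GCSE NVQ2: 3
      NVQ1: 3
      No qualification: 4
  income:
    kind: recode
    source: annual_income_band
    map:
      < £25,999: 1
      £26,000-37,999: 2
      £38,000-59,999: 3
      £60,000+: 4
  type_1_diabetes_diagnosis:
    kind: recode
    source: type_1_diabetes_diagnosis
    map:
      'Yes': 1
      'No': 0
  type_2_diabetes_diagnosis:
    kind: recode
    source: type_2_diabetes_diagnosis
    map:
      'Yes': 1
      'No': 0
  depression_diagnosis:
    kind: recode
    source: depression_diagnosis
    map:
      'Yes': 1
      'No': 0
  self_report_visual_difficulty:
    kind: recode
    source: self_report_visual_difficulty
    map:
      'Yes': 1
      'No': 0
  angina_diagnosis:
    kind: recode
    source: angina_diagnosis
    map:
      'Yes': 1
      'No': 0
  mi_diagnosis:
    kind: recode
    source: mi_diagnosis
    map:
      'Yes': 1
      'No': 0
  hypertension_diagnosis:
    kind: recode
    source: hypertension_diagnosis
    map:
      'Yes': 1
      'No': 0
  stroke_diagnosis:
    kind: recode
    source: stroke_diagnosis
    map:
      'Yes': 1
      'No': 0
  self_report_general_health:
    kind: recode
    source: self_report_general_health
    map:
      'Yes': 1
      'No': 0
  medications:
    kind: identity
    source: medications
  ghq_score:
    kind: identity
    source: ghq_score
  depression_score:
    kind: identity
    source: depression_score
  job_satisfaction_score:
    kind: identity
    source: job_satisfaction_score
  immediate_recall_score:
    kind: standardise
    source: immediate_recall_score
  delayed_recall_score:
    kind: standardise
    source: delayed_recall_score
  digit_symbol_substitution_score:
    kind: standardise
    source: digit_symbol_substitution_score
  choice_reaction_time:
    kind: standardise
    source: crt_msec
  alcohol_consumption:
    kind: units_or_other
    source: alcohol_units_week
  smoking_status:
    kind: recode
    source: smoking
    map:
      Never: 0
      Ex: 1
      Current: 2
  vigorous_exercise:
    kind: recode
    source: vigorous_exercise
    map:
      'Yes': 1
      'No': 0
  accommodation_type:
    kind: recode
    source: accommodation
    map:
      House/bungalow: 1
      Flat: 2
      Sheltered housing: 3
      Other: 4
  height:
    kind: identity
    source: height
  weight:
    kind: identity
    source: weight
  bmi:
    kind: identity
    source: bmi
  systolic_bp:
    kind: identity
    source: systolic_bp
  diastolic_bp:
    kind: identity
    source: diastolic_bp
  haemoglobin:
    kind: identity
    source: haemoglobin
  white_cell_count:
    kind: identity
    source: white_cell_count
  rbc_count:
    kind: identity
    source: rbc_count
  total_cholesterol:
    kind: identity
    source: total_cholesterol
  hdl_cholesterol:
    kind: identity
    source: hdl_cholesterol
  creatinine:
    kind: identity
    source: creatinine
  glucose:
    kind: identity
    source: glucose
  cortisol_decrease:
    kind: identity
    source: cortisol_decrease
  apoe_status:
    kind: apoe
    source: apoe_genotype
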