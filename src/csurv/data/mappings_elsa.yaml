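cohort_id: elsa
display_name: English Longitudinal Study of Ageing
currency: GBP
rules:
  cohort_id:
    kind: identity
    source: cohort_id
  assessment_date:
    kind: date_truncate
    source: assessment_date
    dialect: uk
  date_of_birth:
    kind: date_truncate
    source: date_of_birth
    dialect: uk
  date_of_death:
    kind: date_truncate
    source: date_of_death
    dialect: uk
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
      Non white: 5
  cohabitation:
    kind: recode
    source: marital_status
    map:
      Single: 1
      Married: 2
      Remarried: 2
      Cohabiting: 2
      Divorced: 3
      Separated: 3
      Widowed: 4
      Other: 5
  years_education:
    kind: identity
    source: years_education
  educational_level:
    kind: recode
    source: highest_qualification
    map:
      Deg. Equiv: 2
      Higher ed: 3
      NVQ3: 3
      NVQ2: 3
      NVQ1: 3
      No qualification: 4
  income:
    kind: quantile
    source: annual_income_gbp
  childhood_physical_abuse:
    kind: recode
    source: childhood_physical_abuse
    map:
      'Yes': 1
      'No': 0
  adolescent_physical_abuse:
    kind: recode
    source: adolescent_physical_abuse
    map:
      'Yes': 1
      'No': 0
  sexual_abuse:
    kind: recode
    source: sexual_abuse
    map:
      'Yes': 1
      'No': 0
  parental_smoking:
    kind: recode
    source: parental_smoking
    map:
      'Yes': 1
      'No': 0
  type_1_diabetes_diagnosis:
    kind: date_presence
    source: type_1_diabetes_diagnosis_date
    dialect: uk
  type_2_diabetes_diagnosis:
    kind: date_presence
    source: type_2_diabetes_diagnosis_date
    dialect: uk
  ad_diagnosis:
    kind: date_presence
    source: ad_diagnosis_date
    dialect: uk
  pd_diagnosis:
    kind: date_presence
    source: pd_diagnosis_date
    dialect: uk
  depression_diagnosis:
    kind: score_threshold
    source: cesd_score
    threshold: 4
    direction: ge
  self_report_visual_difficulty:
    kind: recode
    source: self_report_visual_difficulty
    map:
      'Yes': 1
      'No': 0
  angina_diagnosis:
    kind: date_presence
    source: angina_diagnosis_date
    dialect: uk
  mi_diagnosis:
    kind: date_presence
    source: mi_diagnosis_date
    dialect: uk
  hypertension_diagnosis:
    kind: date_presence
    source: hypertension_diagnosis_date
    dialect: uk
  stroke_diagnosis:
    kind: date_presence
    source: stroke_diagnosis_date
    dialect: uk
  arthritis_diagnosis:
    kind: date_presence
    source: arthritis_diagnosis_date
    dialect: uk
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
  self_report_depression:
    kind: recode
    source: self_report_depression
    map:
      'Yes': 1
      'No': 0
  depression_score:
    kind: identity
    source: depression_score
  epq_neuroticism:
    kind: identity
    source: epq_neuroticism
  epq_extraversion:
    kind: identity
    source: epq_extraversion
  life_satisfaction_score:
    kind: identity
    source: life_satisfaction_score
  job_satisfaction_score:
    kind: identity
    source: job_satisfaction_score
  immediate_recall_score:
    kind: standardise
    source: immediate_recall_score
  delayed_recall_score:
    kind: standardise
    source: delayed_recall_score
  verbal_fluency_score:
    kind: standardise
    source: verbal_fluency_score
  fluid_intelligence_score:
    kind: standardise
    source: numeracy_score
  mmse_score:
    kind: identity
    source: mmse_score
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
    kind: proxy_condition
    source: sports_club_gym
    trigger: 'Yes'
  moderate_exercise:
    kind: score_threshold
    source: moderate_exercise_days_week
    threshold: 1
    direction: ge
  walking:
    kind: score_threshold
    source: walking_days_week
    threshold: 1
    direction: ge
  sleep_quality_scale:
    kind: identity
    source: sleep_quality_scale
  sleep_hours:
    kind: identity
    source: sleep_hours
  adl_score:
    kind: identity
    source: adl_score
  iadl_score:
    kind: identity
    source: iadl_score
  number_of_house_occupants:
    kind: identity
    source: number_of_house_occupants
  number_of_rooms:
    kind: identity
    source: number_of_rooms
  social_contacts_per_month:
    kind: identity
    source: social_contacts_per_month
  social_media_sites_used:
    kind: identity
    source: social_media_sites_used
  social_media_use_daily:
    kind: identity
    source: social_media_use_daily
  height:
    kind: identity
    source: height
  weight:
    kind: identity
    source: weight
  bmi:
    kind: identity
    source: bmi
  grip_strength:
    kind: identity
    source: grip_strength
  gait_speed:
    kind: identity
    source: gait_speed
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
  crp:
    kind: identity
    source: crp
  apoe_status:
    kind: apoe
    source: apoe_genotype
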