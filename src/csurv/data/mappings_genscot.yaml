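cohort_id: genscot
display_name: Generation Scotland
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
  date_of_death:
    kind: date_truncate
    source: date_of_death
    dialect: iso
  dna_extracted:
    kind: identity
    source: dna_extracted
  plasma_collected:
    kind: identity
    source: plasma_collected
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
      Other: 5
  cohabitation:
    kind: recode
    source: living_as_couple
    map:
      'Yes': 2
      'No': 1
  years_education:
    kind: identity
    source: years_education
  educational_level:
    kind: recode
    source: highest_qualification
    map:
      College/Uni: 2
      Highers: 3
      Standards: 3
      CSE equivalent: 3
      Certificate: 4
      No qualification: 4
  income:
    kind: quantile
    source: annual_income_gbp
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
  angina_diagnosis:
    kind: proxy_condition
    source: heart_disease
    trigger: 'Yes'
  mi_diagnosis:
    kind: proxy_condition
    source: heart_disease
    trigger: 'Yes'
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
  head_injury:
    kind: recode
    source: head_injury
    map:
      'Yes': 1
      'No': 0
  copd_diagnosis:
    kind: recode
    source: copd_diagnosis
    map:
      'Yes': 1
      'No': 0
  medications:
    kind: identity
    source: medications
  dementia_parent:
    kind: recode
    source: dementia_parent
    map:
      'Yes': 1
      'No': 0
  dementia_grandparent:
    kind: recode
    source: dementia_grandparent
    map:
      'Yes': 1
      'No': 0
  dementia_sibling:
    kind: recode
    source: dementia_sibling
    map:
      'Yes': 1
      'No': 0
  ad_parent:
    kind: recode
    source: ad_parent
    map:
      'Yes': 1
      'No': 0
  ad_grandparent:
    kind: recode
    source: ad_grandparent
    map:
      'Yes': 1
      'No': 0
  ad_sibling:
    kind: recode
    source: ad_sibling
    map:
      'Yes': 1
      'No': 0
  vad_grandparent:
    kind: recode
    source: vad_grandparent
    map:
      'Yes': 1
      'No': 0
  pd_parent:
    kind: recode
    source: pd_parent
    map:
      'Yes': 1
      'No': 0
  pd_grandparent:
    kind: recode
    source: pd_grandparent
    map:
      'Yes': 1
      'No': 0
  pd_sibling:
    kind: recode
    source: pd_sibling
    map:
      'Yes': 1
      'No': 0
  chd_parent:
    kind: recode
    source: chd_parent
    map:
      'Yes': 1
      'No': 0
  chd_grandparent:
    kind: recode
    source: chd_grandparent
    map:
      'Yes': 1
      'No': 0
  chd_sibling:
    kind: recode
    source: chd_sibling
    map:
      'Yes': 1
      'No': 0
  stroke_parent:
    kind: recode
    source: stroke_parent
    map:
      'Yes': 1
      'No': 0
  stroke_grandparent:
    kind: recode
    source: stroke_grandparent
    map:
      'Yes': 1
      'No': 0
  ghq_score:
    kind: identity
    source: ghq_score
  depression_score:
    kind: identity
    source: depression_score
  epq_neuroticism:
    kind: identity
    source: epq_neuroticism
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
    kind: smoking_two_field
    ever_source: ever_smoked
    current_source: currently_smoking
  number_of_house_occupants:
    kind: identity
    source: number_of_house_occupants
  number_of_rooms:
    kind: identity
    source: number_of_rooms
  accommodation_type:
    kind: recode
    source: accommodation
    map:
      House/bungalow: 1
      Apartment/flat: 2
      Hostel: 3
      Care home: 3
      Mobile/caravan: 4
      Religious community: 4
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
  total_cholesterol:
    kind: identity
    source: total_cholesterol
  hdl_cholesterol:
    kind: identity
    source: hdl_cholesterol
  glucose:
    kind: identity
    source: glucose
  apoe_status:
    kind: apoe
    source: apoe_genotype
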