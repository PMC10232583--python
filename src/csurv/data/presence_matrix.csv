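variable_id,airwave,elsa,genscot,memento
cohort_id,1,1,1,1
assessment_date,1,1,1,1
date_of_birth,1,1,1,1
date_of_death,0,1,1,1
cause_of_death,0,0,0,1
dna_extracted,1,1,1,1
plasma_collected,1,1,1,1
serum_collected,1,1,0,1
csf_collected,0,0,0,1
age,1,1,1,1
gender,1,1,1,1
ethnicity,1,1,1,0
cohabitation,1,1,1,1
years_education,0,1,1,1
educational_level,1,1,1,1
income,1,1,1,1
childhood_physical_abuse,0,1,0,0
adolescent_physical_abuse,0,1,0,0
sexual_abuse,0,1,0,0
parental_smoking,0,1,0,0
type_1_diabetes_diagnosis,1,1,1,1
type_2_diabetes_diagnosis,1,1,1,1
ad_diagnosis,0,1,0,1
ad_ftd_diagnosis,0,0,0,1
ad_mixed_diagnosis,0,0,0,1
vad_diagnosis,0,0,0,1
pd_diagnosis,0,1,0,1
depression_diagnosis,1,1,1,1
self_report_visual_difficulty,1,1,0,0
self_report_hearing_difficulty,0,0,0,1
angina_diagnosis,1,1,1,1
mi_diagnosis,1,1,1,1
hypertension_diagnosis,1,1,1,1
stroke_diagnosis,1,1,1,1
head_injury,0,0,1,1
copd_diagnosis,0,0,1,1
arthritis_diagnosis,0,1,0,1
current_pain,0,0,0,1
self_report_general_health,1,1,0,0
medications,1,1,1,1
dementia_parent,0,0,1,1
dementia_grandparent,0,0,1,0
dementia_sibling,0,0,1,1
ad_parent,0,0,1,1
ad_grandparent,0,0,1,0
ad_sibling,0,0,1,1
vad_parent,0,0,0,1
vad_grandparent,0,0,1,0
vad_sibling,0,0,0,1
pd_parent,0,0,1,1
pd_grandparent,0,0,1,0
pd_sibling,0,0,1,1
chd_parent,0,0,1,1
chd_grandparent,0,0,1,0
chd_sibling,0,0,1,1
stroke_parent,0,0,1,1
stroke_grandparent,0,0,1,0
stroke_sibling,0,0,0,1
ghq_score,1,1,1,1
self_report_depression,0,1,0,1
loss_of_interest,0,0,0,1
depression_score,1,1,1,1
epq_neuroticism,0,1,1,0
epq_extraversion,0,1,0,0
life_satisfaction_score,0,1,0,0
job_satisfaction_score,1,1,0,0
quality_of_life_score,0,0,0,1
loneliness_scale_score,0,0,0,0
immediate_recall_score,1,1,1,1
delayed_recall_score,1,1,1,1
digit_symbol_substitution_score,1,0,1,0
verbal_fluency_score,0,1,0,1
choice_reaction_time,1,0,1,0
fluid_intelligence_score,0,1,0,0
mmse_score,0,1,0,1
adas_cog_total_score,0,0,0,0
cdr_total_score,0,0,0,1
subjective_memory_complaint,0,0,0,1
mci_diagnosis,0,0,0,0
alcohol_consumption,1,1,1,1
smoking_status,1,1,1,1
vigorous_exercise,1,1,0,1
moderate_exercise,0,1,0,1
walking,0,1,0,1
sleep_quality_scale,0,1,0,0
sleep_hours,0,1,0,1
adl_score,0,1,0,1
iadl_score,0,1,0,1
number_of_house_occupants,0,1,1,1
number_of_rooms,0,1,1,0
accommodation_type,1,0,1,1
pollution_grime,0,0,0,0
social_contacts_per_month,0,1,0,0
social_media_sites_used,0,1,0,0
social_media_use_daily,0,1,0,0
height,1,1,1,1
weight,1,1,1,1
bmi,1,1,1,1
grip_strength,0,1,0,0
gait_speed,0,1,0,1
systolic_bp,1,1,1,1
diastolic_bp,1,1,1,1
white_matter_volume,0,0,0,1
grey_matter_volume,0,0,0,1
left_hippocampal_volume,0,0,0,1
right_hippocampal_volume,0,0,0,1
wm_hyperintensities,0,0,0,1
amyloid_pib_suvr,0,0,0,1
haemoglobin,1,1,1,1
white_cell_count,1,1,0,1
rbc_count,1,1,0,1
total_cholesterol,1,1,1,1
hdl_cholesterol,1,1,1,1
creatinine,1,1,0,1
glucose,1,1,1,1
crp,0,1,0,0
cortisol_decrease,1,0,0,0
abeta_42_plasma,0,0,0,1
abeta_40_plasma,0,0,0,1
abeta_42_csf,0,0,0,1
abeta_40_csf,0,0,0,1
total_tau,0,0,0,1
p_tau,0,0,0,1
apoe_status,1,1,1,1
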