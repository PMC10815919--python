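patient_age
last_wbc_count
last_cretenine_preop
BPsystolic
last_hematocrit
Cardiac_Presentation_on_Admission
Statin
Mitral_regurgitation
diastolic
gender_id
CABG_status
nitratesIV
family_history_of_Cardiac_disease
beta_blockers
arrhythmia
lipid_lowering
Prior_PCI
Cerebovascular_disease
Pulmonary_insuff
MI_timing
inotropes
Angina_class
PCI_timing
congestive_heart_failure
adp_inhibitors_within_5days
cardiogenic_shock
intracardiac_device
pulmonary_artery_hypertension
NYHA_class
Arrhythmia_Type_Sust_VT_VF
myocardial_infarction
resuscitation
dialysis
steroids
previous_coronary_bypass
previous_valve
FirstCVSurgery
warfarin
ace_inhibitors
Carotid_disease
aspirin
left_main_disease
bronchodilators
Coronaries_diseased
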