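# Example threshold override file for `malnutdx diagnose --thresholds ...`
# Keys mirror the CriteriaThresholds field names; omitted keys keep their
# defaults. Units are fixed (kg/m^2, cm, kg, g/L, percent, years).

nrs_cutoff: 3
age_pivot: 70.0

# GLIM phenotypic (Asian BMI cutoffs)
glim_bmi_young: 18.5
glim_bmi_old: 20.0
glim_severe_bmi_young: 17.8
glim_severe_bmi_old: 17.0
glim_wl_moderate_6mo: 5.0
glim_wl_moderate_beyond: 10.0
glim_wl_severe_6mo: 10.0
glim_wl_severe_beyond: 20.0

# Muscle-mass surrogates (AWGS 2019)
calf_cutoff_male: 34.0
calf_cutoff_female: 33.0
grip_cutoff_male: 28.0
grip_cutoff_female: 18.0

# Inflammation surrogate
albumin_inflammation: 35.0

# ESPEN 2015
espen_bmi_abs: 18.5
espen_bmi_young: 20.0
espen_bmi_old: 22.0

# Bedside 8-item scale
sga_items_required: 5
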