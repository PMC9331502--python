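"""Published summary statistics the synthetic generator is calibrated to.

These anchors describe a multicentre Chinese elderly-inpatient cohort
(n = 2526, tertiary-A hospitals) whose group-wise distributions the
generator emulates. They are targets for marginal/stratum summaries, not a
joint distribution: any joint structure beyond the latent-severity
construction in :mod:`malnutdx.synthetic` is deliberately minimal.

All units follow the cohort dialect: cm, kg, kg/m^2, g/L, 1e9/L, mmol/L,
days, USD. "mal"/"normal" strata refer to the GLIM split unless noted.
"""

# Demographics (whole cohort)
AGE_MEAN = 74.63
AGE_SD = 7.12
AGE_FLOOR = 65.0
MALE_FRAC = 0.592
MARRIED_FRAC = 0.942
EDUCATION_PROBS = {
    "primary_or_lower": 0.718,
    "high_school": 0.131,
    "bachelor_or_above": 0.151,
}

# Admission reasons (cohort fractions; "other" absorbs the remainder)
DISEASE_MIX = {
    "tumor": 0.3753,
    "digestive": 0.1833,
    "nervous": 0.1702,
    "respiratory": 0.0883,
    "osteoarthropathy": 0.0558,
    "cardiovascular": 0.0546,
    "endocrine": 0.0249,
    "kidney": 0.0040,
    "other": 0.0436,
}

# Diagnostic prevalence targets (fractions of the cohort)
PREV_GLIM = 0.379
PREV_SGA = 0.328
PREV_ESPEN = 0.170
SGA_SEVERE_FRAC = 0.148  # severe fraction among SGA-malnourished (123/829)

# Anthropometrics: (malnourished mean, sd), (normal mean, sd) on the GLIM split
HEIGHT = (164.2, 8.3)  # sexes pooled; no stratum contrast modelled
BMI_ESPEN_POS = (18.17, 1.89)  # ESPEN-malnourished stratum
BMI_GLIM_ONLY = (23.1, 2.8)  # GLIM+ but ESPEN- (back-computed from stratum means)
BMI_NORMAL = (24.06, 3.14)
CALF_LOW = (30.7, 3.0)
CALF_NORMAL = (33.7, 3.9)
GRIP_LOW_MALE = (22.0, 4.5)
GRIP_LOW_FEMALE = (14.0, 3.0)
GRIP_NORMAL_MALE = (33.0, 6.0)
GRIP_NORMAL_FEMALE = (22.0, 4.0)
MID_ARM = {"mal": (25.04, 3.97), "normal": (27.39, 3.27)}

# Laboratory values by GLIM stratum: (mal mean, mal sd), (normal mean, normal sd)
LABS = {
    "albumin_g_L": ((35.80, 5.37), (39.74, 4.53)),
    "hemoglobin_g_L": ((115.42, 21.95), (126.92, 18.05)),
    "total_protein_g_L": ((63.60, 7.29), (66.63, 6.43)),
    "prealbumin_g_L": ((0.21, 0.09), (0.24, 0.07)),
    "triglyceride_mmol_L": ((1.47, 1.30), (2.16, 2.22)),
    "cholesterol_mmol_L": ((3.94, 1.36), (4.18, 1.51)),
}
# Lymphocytes are right-skewed: (median, quartile deviation) per stratum
LYMPHOCYTES_MAL = (1.30, 0.46)
LYMPHOCYTES_NORMAL = (1.66, 0.58)

# Outcome model (GLIM stratum)
BASELINE_COMPLICATION_P = 0.027  # complication incidence, GLIM-normal stratum
OR_GLIM_COMPLICATION = 2.414  # adjusted conditional odds ratio
OR_MALE = 1.45
OR_MARRIED = 0.70
OR_AGE_PER_YEAR = 1.0
INFECTIOUS_FRAC = 0.602  # infectious share among complications (62/103)

LOS_MAL = (15.01, 6.83)  # mean, sd (days); window [7, 30] enforced downstream
LOS_NORMAL = (13.89, 6.01)
LOS_WINDOW = (7.0, 30.0)
EXPENSES_MEDIAN_MAL = 3265.59
EXPENSES_MEDIAN_NORMAL = 3242.81
EXPENSES_SIGMA = 0.75  # lognormal shape, both strata
ICU_FRAC = 0.064
MORTALITY_MAL = 0.0105
MORTALITY_NORMAL = 0.0005
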