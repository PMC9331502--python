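# Cohort CSV data dictionary

UTF-8 CSV with a header row, one patient per row. Missing values are
empty cells (never 0). Booleans are written `1`/`0` and parsed from
`1/0/true/false/yes/no`. Column names can be remapped through a schema
file (`canonical_name: actual_name`, YAML or JSON); unknown extra columns
are preserved on round trips.

## Identification and demographics

| column | type | notes |
|---|---|---|
| `patient_id` | string | opaque identifier (mandatory) |
| `age` | years | mandatory; study filter keeps ≥ 65 |
| `sex` | `male` / `female` | mandatory |
| `marital_status` | `married` / `other` | |
| `education` | `primary_or_lower` / `high_school` / `bachelor_or_above` | |
| `admission_reason` | `tumor`, `digestive`, `nervous`, `respiratory`, `cardiovascular`, `osteoarthropathy`, `endocrine`, `kidney`, `other` | |

## Screening and anthropometrics

| column | type | notes |
|---|---|---|
| `nrs2002_total` | integer 0–7 | NRS-2002 total score; ≥ 3 = at nutritional risk |
| `height_cm` | cm > 0 | |
| `weight_kg` | kg > 0 | |
| `bmi_kg_m2` | kg/m² | derived from weight/height when absent; recorded value preferred, disagreement > 0.5 kg/m² flagged |
| `weight_loss_pct_6mo` | percent ≥ 0 | body-weight loss within the past 6 months |
| `weight_loss_pct_beyond_6mo` | percent ≥ 0 | loss over a horizon beyond 6 months |
| `unintentional_weight_loss` | bool | used by the ESPEN 2015 route 2 |
| `calf_circumference_cm` | cm > 0 | muscle-mass surrogate (cutoffs 34/33 cm M/F) |
| `grip_strength_kg` | kg ≥ 0 | muscle-mass surrogate (cutoffs 28/18 kg M/F) |
| `mid_arm_circumference_cm` | cm > 0 | descriptive |

## Laboratory values

`albumin_g_L` (inflammation surrogate, cutoff < 35), `hemoglobin_g_L`,
`lymphocytes_1e9_L`, `total_protein_g_L`, `prealbumin_g_L`,
`triglyceride_mmol_L`, `cholesterol_mmol_L` — all real-valued, all
optional.

## Intake and disease-burden flags

| column | notes |
|---|---|
| `intake_reduced_gt50pct_1wk` | energy intake reduced > 50% for > 1 week |
| `intake_reduced_gt2wk` | intake reduced for > 2 weeks |
| `chronic_gi_disease` | chronic gastrointestinal disease affecting intake/absorption |
| `inflammatory_condition` | acute/chronic inflammation-related disease or injury |

## Subjective global assessment items

Eight columns `sga_<item>`, each rated `A` (normal), `B` or `C`
(severe finding): `weight_change`, `intake_change`, `gi_symptoms`,
`physical_activity`, `disease_nutritional_demand`,
`subcutaneous_fat_loss`, `muscle_atrophy`, `ankle_edema`. Either all
eight are present or all are empty for a given row.

## Outcomes (within 30 days of admission)

| column | type | notes |
|---|---|---|
| `total_complication` | bool | equals infectious OR non-infectious |
| `infectious_complication` | bool | |
| `noninfectious_complication` | bool | |
| `icu_admission` | bool | |
| `icu_days` | days ≥ 0 | > 0 implies `icu_admission` |
| `mortality` | bool | in-hospital death |
| `los_days` | days ≥ 0 | study filter keeps [7, 30] when known |
| `expenses_usd` | USD ≥ 0 | total hospitalization expenses |
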