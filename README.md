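# malnutdx

Rule-based malnutrition diagnostics and outcome-association analysis for
elderly inpatient cohorts.

Malnutrition in hospitalized older adults is diagnosed with several
competing criteria that frequently disagree. This package implements, as
tested and reusable code, the three most common bedside frameworks and the
statistics used to compare them:

* **GLIM** — malnourished iff, after a positive NRS-2002 screen
  (total score ≥ 3), at least one *phenotypic* criterion (weight loss
  > 5% in 6 months or > 10% beyond; low BMI with Asian age-specific
  cutoffs 18.5 / 20 kg/m²; low muscle mass via AWGS 2019 calf-circumference
  < 34/33 cm or grip-strength < 28/18 kg surrogates) **and** one
  *etiologic* criterion (reduced intake / impaired absorption, or
  inflammation — disease burden or serum albumin < 35 g/L) fire, with a
  moderate/severe grade.
* **SGA** — eight A/B/C-rated history and examination items; malnourished
  iff ≥ 5 items rate B or C.
* **ESPEN 2015** — after the same screen, BMI < 18.5 kg/m², or
  unintentional weight loss with age-adjusted BMI (< 20 below 70 y,
  < 22 at or above).

Around the classifiers the package provides:

* **Concordance statistics** — 2×2 cross-classification; sensitivity,
  specificity and accuracy with Wilson score intervals; Cohen's kappa
  `κ = (p_o − p_e)/(1 − p_e)` with a delta-method (Fleiss–Cohen–Everitt)
  or bootstrap CI, plus the conventional interpretation bands
  (0.8–1 "excellent", 0.6–0.8 "good", …).
* **Outcome association** — malnourished-vs-normal group comparisons with
  a Shapiro–Wilk normality gate (χ²/Fisher, Student's t, Mann–Whitney U),
  Spearman covariate screening, multivariable logistic regression
  (adjusted odds ratios for in-hospital complications controlling for
  age, gender, marital status) and random-forest importance (mean
  decrease in accuracy and in Gini).
* **A synthetic cohort generator** calibrated to an emulated multicentre
  elderly-inpatient cohort (n = 2526, age 74.63 ± 7.12 y, 59.2% male,
  diagnostic prevalences ≈ 37.9% / 32.8% / 17.0% with nested positives),
  so every stage runs and is testable with no external data.

See `docs/methods.md` for the model details and `docs/data_dictionary.md`
for the cohort CSV dialect.

## Worked example

```python
import malnutdx as m

cohort, report = m.generate_cohort(m.CohortConfig(seed=1))
dx = m.diagnose_all(cohort)
print(m.prevalence_summary(dx).to_string(index=False))
```

```
criterion      stratum  count   percent
     GLIM malnourished    972 38.479810
     GLIM     moderate    567 22.446556
     GLIM       severe    405 16.033254
      SGA malnourished    837 33.135392
      SGA     moderate    713 28.226445
      SGA       severe    124  4.908947
ESPEN2015 malnourished    431 17.062549
```

The realized prevalences are binomial draws around the configured targets
(37.9% GLIM, 32.8% SGA, 17.0% ESPEN 2015). Agreement of GLIM against the
bedside SGA as reference:

```python
print(m.concordance_report(dx, "GLIM", "SGA").summary())
```

```
Concordance GLIM vs SGA  (n=2526; a=837, b=135, c=0, d=1554)
  accuracy    94.66% (93.71%, 95.47%)
  sensitivity 100.00% (99.54%, 100.00%)
  specificity 92.01% (90.62%, 93.21%)
  kappa       0.884 (0.865, 0.903)  [excellent]
```

Every SGA-malnourished patient is also GLIM-malnourished (c = 0, so
sensitivity is 100%), and the chance-corrected agreement is excellent.
Finally, the adjusted association of GLIM malnutrition with in-hospital
complications:

```python
df = cohort.assign(glim_status=dx["glim_status"])
print(m.fit_logistic(df, "glim_status").summary())
```

```
Logistic model Model1_GLIM (n=2526)
  intercept        OR 0.047 (0.004-0.548)  p=0.01465
  malnutrition     OR 2.386 (1.578-3.606)  p=3.73e-05
  age              OR 0.983 (0.954-1.013)  p=0.2585
  gender           OR 1.579 (1.025-2.434)  p=0.03846
  married          OR 1.568 (0.567-4.337)  p=0.3865
```

The estimated odds ratio 2.386 recovers the generator's planted
conditional OR of 2.414 for malnutrition within sampling error.

The same pipeline is scriptable from the shell:

```bash
malnutdx simulate --n 2526 --seed 1 --out cohort.csv
malnutdx diagnose --input cohort.csv --out dx.csv
malnutdx concord --dx dx.csv --test GLIM --ref SGA
malnutdx report --input cohort.csv --out report.txt
```

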