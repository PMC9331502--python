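# Methods

This note documents the models, conventions and numerical choices behind
`malnutdx`, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Diagnostic engines

All three classifiers operate on a single patient record (or, vectorized,
on a cohort table) and share these conventions:

**Strict comparisons at printed precision.** Clinical cutoffs are exact by
convention: `BMI < 18.5` does not fire at 18.5, `albumin < 35 g/L` does
not fire at 35.0, and `NRS-2002 ≥ 3` does pass at 3. No epsilon fuzzing is
applied at thresholds. All cutoffs live in `CriteriaThresholds` (units:
kg/m², cm, kg, g/L, percent, years; no automatic unit conversion) and can
be overridden from a YAML/JSON file.

**Screening gate.** GLIM and ESPEN 2015 diagnose only patients at
nutritional risk (NRS-2002 total ≥ 3); the NRS-2002 total is an input
field — item-level scoring of the screening scale is out of scope. SGA has
no screening step.

**Missing data policy.** A missing value is `None`/NaN, never 0. Under the
default *lenient* policy a rule whose inputs are missing simply cannot
fire; under *strict*, missing mandatory inputs (NRS total, age, BMI) raise
a typed error (scalar API) or fail the whole cohort call. Records without
weight/height are expected to be removed upstream by the study filters
(age ≥ 65, length of stay within [7, 30] days when known, anthropometrics
present), which mirrors the emulated study's exclusion rules.

**GLIM.** Malnourished iff ≥ 1 phenotypic and ≥ 1 etiologic criterion fire
after a positive screen. Three decisions were genuinely open:

* *Weight-loss thresholds.* The source framework's published wording on
  the "beyond 6 months" horizon is internally inconsistent; we follow the
  consensus reading — moderate: > 5% within 6 months or > 10% beyond;
  severe: > 10% within 6 months or > 20% beyond — with every threshold
  configurable.
* *Muscle-mass surrogate combination.* Calf circumference and grip
  strength are alternative indicators; whether both or either must be low
  is unstated. Default is OR (either suffices), which maximizes
  sensitivity; AND is available via `muscle_rule="and"`.
* *Severity.* Severe iff weight loss > 10% (6 mo) or > 20% (beyond), or
  BMI below the age-specific severe cutoff (17.8 / 17.0 kg/m²); else
  moderate.

**SGA.** Malnourished iff ≥ 5 of 8 items rate B or C. The published scale
does not state where the moderate/severe boundary lies; we grade severe
iff ≥ 5 items rate C, else moderate. This is a pluggable convention, not a
property of the scale, and severity grades are never used in the
concordance statistics (which compare any-malnutrition vs none).

**ESPEN 2015.** Route 1: BMI < 18.5 kg/m². Route 2: unintentional weight
loss and age-adjusted BMI (< 20 below 70 y, < 22 at or above). The
framework gives no quantitative threshold for "unintentional weight
loss"; the recorded boolean flag is used as-is. The fat-free-mass-index
pathway of the original consensus is not implemented (no body-composition
data in the emulated setting). ESPEN 2015 is not severity-graded.

The scalar per-record functions are the reference implementation; the
vectorized `diagnose_all` path is property-tested against them row by row
on randomly generated records.

## Concordance statistics

All agreement statistics derive from the 2×2 table (a, b, c, d) of a test
criterion against a reference criterion (conventionally SGA as the
semi-gold standard):

* sensitivity a/(a+c), specificity d/(b+d), accuracy (a+d)/n; zero
  denominators yield NaN ("undefined"), never 0.
* **Wilson score intervals** for all proportions, without continuity
  correction, with the z-quantile computed from the normal distribution
  (so alternative levels work). The Wilson interval is exact at the
  boundaries — for x = n successes the lower bound is n/(n + z²) — which
  is what makes degenerate 100%-sensitivity rows reportable; the
  Clopper–Pearson interval gives visibly different boundary values and is
  not used.
* **Cohen's kappa** from the marginal-product chance agreement. In the
  fully degenerate case p_e = 1 (all mass in one cell), observed agreement
  is also perfect and kappa is reported as 1.0 by convention.
* **Kappa CI**: delta-method (Fleiss–Cohen–Everitt) standard error by
  default, `kappa ± z·SE` clamped to [−1, 1]; a multinomial bootstrap is
  available and is cross-checked against the delta interval in the tests.
  At kappa = 1 the delta variance vanishes identically, so the interval is
  the degenerate point (1, 1). No claim is made that this matches the CI
  method of any particular external report (several are in circulation);
  point estimates, not kappa CIs, are the comparable quantities.
* Interpretation bands: [0, 0.2) weak, [0.2, 0.4) low, [0.4, 0.6) medium,
  [0.6, 0.8) good, [0.8, 1] excellent; negative kappa (below-chance) reads
  as weak.

Reports render percentages half-up at 2 decimals and kappa at 3; internal
computation is at full precision.

`generate_confusion_fixtures()` ships the three cross-criteria tables
reconstructed from the reference cohort's published marginal counts
(n = 2526; 956, 829 and 429 positives) combined with its printed 100%
sensitivities/specificities: (829, 127, 0, 1570), (429, 527, 0, 1570) and
(429, 0, 400, 1697). These are arithmetic reconstructions, not data.

## Outcome analyses

**Group comparisons.** Test selection is a pure function of variable type
and, for continuous variables, a Shapiro–Wilk gate at α = 0.05 applied to
each group (on a fixed random subsample above ~5000 values, where the
test statistic is unreliable): normal → Student's t (equal variances),
otherwise Mann–Whitney U. Summaries follow the gate: mean ± SD when
normal, median and quartile deviation (Q3 − Q1)/2 otherwise. Categorical
outcomes use the chi-square test without continuity correction; on a 2×2
table with any expected cell < 5 the Fisher exact test is substituted.
All-identical continuous values make the gate undefined; the comparison is
reported without a test. In the criterion-wise outcome table, binary
outcomes with fewer than 10 events cohort-wide (e.g. in-hospital
mortality at its ≈ 0.4% rate) are reported descriptively with the test
suppressed.

**Logistic models.** One model per criterion: outcome = total in-hospital
complications; terms = malnutrition indicator + age (years, continuous) +
gender (male = 1) + marital status (married = 1). Maximum-likelihood fit
via `statsmodels.Logit` on complete cases (configurable); per-term OR with
Wald 95% CI. Perfect or quasi-separation (including non-convergence and
implausibly large coefficients, |β| > 15) raises a typed `SeparationError`
rather than returning silent garbage; at small n with rare outcomes a few
percent of simulated replicates are expected to be quasi-separated
(typically zero events in the small unmarried stratum) and are excluded
from simulation summaries as "CI undefined".

**Random-forest importance.** A 500-tree forest (scikit-learn defaults
otherwise) is fit on a stratified 75% training partition. *Mean decrease
in accuracy* is computed per tree: the drop in that tree's held-out (25%)
accuracy after permuting one feature column, averaged over trees and then
over split replicates (default 10). The per-tree formulation matters:
with rare outcomes the whole-forest majority vote almost never flips, so
forest-level accuracy permutation is degenerate, while individual fully
grown trees do predict positives. *Mean decrease in Gini* is the per-tree
unnormalized impurity-decrease attribution averaged over the forest. All
randomness (splits, forests, permutations) derives from one seed, so the
report is a deterministic function of (data, config, seed). An
out-of-bag variant is not provided (no public OOB-index API in the
chosen implementation); the held-out partition serves the same purpose.

## Synthetic cohort generator

The generator emulates a multicentre elderly-inpatient cohort: n = 2526,
age 74.63 ± 7.12 y truncated at 65 (the untruncated normal's parameters
are solved numerically at config time so the *post-truncation* moments
match), 59.2% male, 94.2% married, an admission-reason mix led by tumors
(37.5%), digestive (18.3%) and nervous-system disease (17.0%), and
diagnostic prevalence targets 37.9% (GLIM), 32.8% (SGA), 17.0%
(ESPEN 2015).

Construction:

1. One uniform draw per patient assigns a nested latent severity tier
   (ESPEN⁺ ⊆ SGA⁺ ⊆ GLIM⁺) at the target rates — the nesting mirrors the
   empirical structure of the emulated cohort, where the printed 100%
   sensitivities/specificities imply exactly this containment.
2. Observable fields are sampled from tier-conditional distributions
   anchored to the published stratum summaries (BMI 20.90 ± 3.37 vs
   24.06 ± 3.14 on the GLIM split, albumin 35.8 vs 39.7 g/L, …), each
   truncated to respect the diagnostic boundaries of the assigned tier
   with a 0.06 safety margin so that rounding to recorded precision
   cannot flip a value across a strict cutoff. GLIM-negative patients
   split into a phenotypically clean majority and a configurable fraction
   (default 25%) with phenotypic signs but no etiologic criterion, which
   keeps the negative stratum clinically plausible.
3. The 8 A/B/C items are drawn as counts of B/C ratings per tier
   (≥ 5 for the SGA⁺ tier, with a 14.8% severe fraction; 2–4 for
   GLIM⁺/SGA⁻ "borderline" patients; 0–2 otherwise), scattered over the
   items uniformly.
4. Complications follow a logistic model: baseline incidence 2.7% in the
   GLIM-negative stratum, conditional OR 2.414 for GLIM malnutrition, and
   modest covariate effects (male OR 1.45, married OR 0.70, age OR 1.0)
   on covariates centred at their population means. Optional extra
   effects on the SGA/ESPEN tiers support importance experiments.
5. Length of stay is lognormal, moment-matched per stratum
   (15.01 ± 6.83 vs 13.89 ± 6.01 days) and rejection-sampled into the
   [7, 30]-day inclusion window (the truncation shifts the realized
   moments slightly; the stratum contrast direction is preserved and is
   what the tests assert). Expenses are lognormal around the stratum
   medians; ICU transfer (6.4%) and mortality (≈ 1% vs ≈ 0.05% by
   stratum) are generated at their low rates purely to exercise the
   descriptive path.

Because fields are sampled inside the rule boundaries of the assigned
tier, the rule engines recover the tier for every patient: realized
prevalences are binomial around the targets (SD ≈ 1 point at n = 2526),
the screening gate is never violated, and nesting of the *engine outputs*
emerges rather than being asserted. The generation report recomputes all
of this by actually running the engines on the emitted cohort.

**What the generator does not emulate.** Only the published group-wise
(marginal/stratum) distributions are targeted; joint structure beyond the
single latent tier is deliberately minimal. There is no hospital/city
clustering, no measurement error or inter-rater variability in the SGA
items, no missingness (real cohorts have plenty), and no correlation
between labs beyond their common dependence on the tier. Passing tests on
this cohort therefore demonstrate correctness of the *pipeline* under the
stated statistical structure, not performance on real hospital data.

**Importance planting.** `plant_importance_structure` returns a config
with strictly ordered outcome effects on the three indicators. Because
the indicators are nested, the log-odds increments are cumulative, and a
spread-out allocation makes the SGA split as informative as the GLIM
split; the default spec therefore concentrates the risk jump at the GLIM
boundary (OR 4.0, with 1.2 / 1.1 increments) and raises the baseline to
8% so the rare-outcome classifier has signal to learn. Zero-effect specs
are allowed for null experiments; non-strictly-ordered specs are
rejected.

## Problem sizes used in the checks

The acceptance-level checks run at: 200 replicate cohorts of n = 2526 for
median-OR recovery; 2000 replicates of n = 800 for Wald-CI coverage
(≈ 96% of replicates yield a defined CI); 20 seeded runs (500 trees,
5 split replicates) for the importance-ordering property; 10⁵ random
records for the screening-gate implication; all 3⁸ = 6561 rating vectors
for the SGA oracle. These sizes give Monte-Carlo error comfortably inside
the asserted tolerances (e.g. coverage SE ≈ 0.5% at 2000 replicates).

## Known limitations

* The kappa CI method is a package choice; external reports may use
  different (often wider) intervals.
* Real-data regression p-values and adjusted ORs from any particular
  study are not reproducible without that study's individual-level data;
  the package targets them only through parameter-recovery simulation.
* The SGA severity split and the ESPEN "unintentional" flag are
  conventions exposed as configuration, as documented above.
* The generator's negative stratum is cleaner than real life: patients
  with phenotypic signs *and* etiologic criteria but NRS < 3 exist in
  clinics but are rare here by construction.
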