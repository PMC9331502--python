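"""Synthetic elderly-inpatient cohort generator.

Emulates the statistical structure the diagnostic and outcome analyses
assume, so every pipeline stage runs with no external data:

1. a latent nutritional-impairment tier is drawn per patient from one
   uniform variable, giving nested severity strata (ESPEN-positive ⊆
   SGA-positive ⊆ GLIM-positive) at the configured target prevalences;
2. demographics and the admission-reason mix are drawn independently at
   the configured cohort rates;
3. NRS-2002 score, BMI, weight-loss fields, muscle surrogates, intake and
   inflammation fields and the eight A/B/C assessment items are sampled
   from tier-conditional distributions anchored to the published stratum
   summaries, truncated so that they respect the diagnostic rule
   boundaries of the corresponding tier;
4. in-hospital complications follow a logistic model in the GLIM tier and
   the covariates (age, gender, marital status), with optional extra
   planted effects on the SGA/ESPEN tiers for importance experiments;
5. length of stay and expenses are drawn from moment-matched lognormals
   per stratum, ICU transfer and mortality at their low cohort rates.

Because the observable fields are sampled inside the rule boundaries of
the assigned tier, the rule engines recover the tier for every patient and
the realized prevalences are binomial around the targets; the nesting of
the *engine outputs* is an emergent property of tier nesting, not an
asserted constraint.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, special
from scipy.stats import norm, truncnorm

from . import calibration as cal
from .concordance import ConfusionTable2x2
from .diagnostics import diagnose_all
from .io import CANONICAL_COLUMNS
from .records import SGA_ITEM_NAMES
from .thresholds import CriteriaThresholds

DEFAULT_THRESHOLDS = CriteriaThresholds()


class CohortConfig(BaseModel):
    """All generator knobs. Defaults reproduce the emulated study cohort."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=2526, ge=1)
    seed: int = 0

    # demographics
    age_mean: float = cal.AGE_MEAN
    age_sd: float = Field(default=cal.AGE_SD, gt=0)
    age_floor: float = cal.AGE_FLOOR
    male_frac: float = Field(default=cal.MALE_FRAC, ge=0, le=1)
    married_frac: float = Field(default=cal.MARRIED_FRAC, ge=0, le=1)

    # diagnostic prevalence targets (cohort fractions)
    prev_glim: float = Field(default=cal.PREV_GLIM, ge=0, le=1)
    prev_sga: float = Field(default=cal.PREV_SGA, ge=0, le=1)
    prev_espen: float = Field(default=cal.PREV_ESPEN, ge=0, le=1)
    sga_severe_frac: float = Field(default=cal.SGA_SEVERE_FRAC, ge=0, le=1)
    #: NRS-2002 at-risk probability among GLIM-negative patients
    nrs_risk_frac_negatives: float = Field(default=0.25, ge=0, le=1)
    #: fraction of GLIM-negative patients with phenotypic signs but no
    #: etiologic criterion (keeps the negative stratum clinically plausible)
    pheno_only_frac_negatives: float = Field(default=0.25, ge=0, le=1)

    # outcome model (log-odds are taken of these ORs; covariates centred)
    baseline_complication_p: float = Field(
        default=cal.BASELINE_COMPLICATION_P, gt=0, lt=1
    )
    or_glim: float = Field(default=cal.OR_GLIM_COMPLICATION, gt=0)
    or_sga: float = Field(default=1.0, gt=0)  # extra effect on top of GLIM
    or_espen: float = Field(default=1.0, gt=0)  # extra effect on top of SGA
    or_male: float = Field(default=cal.OR_MALE, gt=0)
    or_married: float = Field(default=cal.OR_MARRIED, gt=0)
    or_age_per_year: float = Field(default=cal.OR_AGE_PER_YEAR, gt=0)
    infectious_frac: float = Field(default=cal.INFECTIOUS_FRAC, ge=0, le=1)

    # secondary outcomes
    los_mal: tuple[float, float] = cal.LOS_MAL
    los_normal: tuple[float, float] = cal.LOS_NORMAL
    los_window: tuple[float, float] = cal.LOS_WINDOW
    icu_frac: float = Field(default=cal.ICU_FRAC, ge=0, le=1)
    mortality_mal: float = Field(default=cal.MORTALITY_MAL, ge=0, le=1)
    mortality_normal: float = Field(default=cal.MORTALITY_NORMAL, ge=0, le=1)

    @model_validator(mode="after")
    def _check_feasible(self) -> "CohortConfig":
        if not self.prev_espen <= self.prev_sga <= self.prev_glim:
            raise ValueError(
                "infeasible prevalence targets: require ESPEN <= SGA <= GLIM "
                f"(got {self.prev_espen}, {self.prev_sga}, {self.prev_glim})"
            )
        if self.age_floor >= self.age_mean:
            raise ValueError("age_floor must lie below age_mean")
        return self


@dataclass
class GenerationReport:
    """Realized properties of one generated cohort (engine-verified)."""

    n: int
    seed: int
    prevalence_glim: float
    prevalence_sga: float
    prevalence_espen: float
    nesting_violations_sga_glim: int  # SGA+ but GLIM- (engine outputs)
    nesting_violations_espen_glim: int
    gate_violations: int  # diagnosed malnourished despite NRS < 3
    complication_incidence_glim_pos: float
    complication_incidence_glim_neg: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@lru_cache(maxsize=16)
def _truncated_normal_params(
    mean: float, sd: float, floor: float
) -> tuple[float, float]:
    """(mu, sigma) of an untruncated normal whose left-truncation at
    ``floor`` has the requested mean and sd. Solved numerically."""

    def residual(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        a = (floor - mu) / sigma
        m, v = truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    sol = optimize.root(residual, x0=[mean, np.log(sd)], method="hybr")
    if not sol.success:
        raise RuntimeError(f"age truncation calibration failed: {sol.message}")
    mu, log_sigma = sol.x
    return float(mu), float(np.exp(log_sigma))


def _tn(rng, mean, sd, lo, hi, size) -> np.ndarray:
    """Vectorized truncated-normal draw (bounds may be arrays)."""
    lo = np.broadcast_to(np.asarray(lo, dtype=float), (size,))
    hi = np.broadcast_to(np.asarray(hi, dtype=float), (size,))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_from_moments(rng, mean, sd, size) -> np.ndarray:
    sigma2 = np.log(1 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _rejection_window(draw, lo, hi, max_iter=200) -> np.ndarray:
    """Redraw out-of-window values; falls back to clipping if unlucky."""
    x = draw()
    for _ in range(max_iter):
        bad = (x < lo) | (x > hi)
        if not bad.any():
            return x
        x[bad] = draw()[bad]
    return np.clip(x, lo, hi)


def generate_cohort(
    config: CohortConfig = CohortConfig(),
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, GenerationReport]:
    """Draw one synthetic cohort; returns (cohort frame, generation report).

    The frame uses the canonical cohort dialect of :mod:`malnutdx.io`
    (convert with :func:`malnutdx.io.frame_to_records` for record objects).
    Identical config and seed give a byte-identical CSV. The report's
    prevalences are computed by actually running the rule engines on the
    generated cohort.
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    th = thresholds

    # -- latent severity tiers (nested by construction) -------------------
    u = rng.random(n)
    espen_t = u < cfg.prev_espen
    sga_t = u < cfg.prev_sga
    glim_t = u < cfg.prev_glim
    glim_only = glim_t & ~espen_t  # GLIM+ but ESPEN- (may or may not be SGA+)
    neg = ~glim_t

    # -- demographics ------------------------------------------------------
    mu_age, sigma_age = _truncated_normal_params(cfg.age_mean, cfg.age_sd, cfg.age_floor)
    age = np.round(_tn(rng, mu_age, sigma_age, cfg.age_floor, 105.0, n), 1)
    old = age >= th.age_pivot
    male = rng.random(n) < cfg.male_frac
    sex = np.where(male, "male", "female")
    married = rng.random(n) < cfg.married_frac
    education = rng.choice(
        list(cal.EDUCATION_PROBS), size=n, p=list(cal.EDUCATION_PROBS.values())
    )
    mix = np.array(list(cal.DISEASE_MIX.values()))
    admission = rng.choice(list(cal.DISEASE_MIX), size=n, p=mix / mix.sum())

    # -- NRS-2002 ----------------------------------------------------------
    nrs = np.empty(n, dtype=int)
    nrs[glim_t] = th.nrs_cutoff + np.minimum(rng.poisson(0.9, glim_t.sum()), 4)
    at_risk_neg = rng.random(n) < cfg.nrs_risk_frac_negatives
    idx = neg & at_risk_neg
    nrs[idx] = th.nrs_cutoff + np.minimum(rng.poisson(0.4, idx.sum()), 4)
    idx = neg & ~at_risk_neg
    below = np.arange(th.nrs_cutoff)
    p_below = [0.30, 0.45, 0.25] if th.nrs_cutoff == 3 else None
    nrs[idx] = rng.choice(below, size=idx.sum(), p=p_below)
    nrs = np.clip(nrs, 0, 7)

    # -- BMI / height / weight --------------------------------------------
    espen_cut = np.where(old, th.espen_bmi_old, th.espen_bmi_young)
    glim_cut = np.where(old, th.glim_bmi_old, th.glim_bmi_young)
    # eps keeps draws clear of the strict rule boundaries so that the later
    # rounding of weight/BMI/calf/grip cannot flip a tier across a cutoff
    eps = 0.06
    bmi = np.empty(n)
    m, s = cal.BMI_ESPEN_POS
    bmi[espen_t] = _tn(rng, m, s, 13.0, espen_cut[espen_t] - eps, espen_t.sum())
    m, s = cal.BMI_GLIM_ONLY
    bmi[glim_only] = _tn(rng, m, s, espen_cut[glim_only] + eps, 42.0, glim_only.sum())
    # negative stratum: subgroup B may show phenotypic signs (but never an
    # etiologic criterion); subgroup A is phenotypically clean
    pheno_only = neg & (rng.random(n) < cfg.pheno_only_frac_negatives)
    clean_neg = neg & ~pheno_only
    m, s = cal.BMI_NORMAL
    bmi[clean_neg] = _tn(rng, m, s, glim_cut[clean_neg] + eps, 42.0, clean_neg.sum())
    bmi[pheno_only] = _tn(
        rng, 22.5, 3.0, th.espen_bmi_abs + eps, 42.0, pheno_only.sum()
    )
    height = np.round(np.clip(rng.normal(*cal.HEIGHT, n), 140.0, 195.0), 1)
    weight = np.round(bmi * (height / 100.0) ** 2, 2)
    bmi = weight / (height / 100.0) ** 2  # keep the recorded triple consistent

    # -- weight loss -------------------------------------------------------
    wl6 = np.zeros(n)
    wl_beyond = np.zeros(n)
    unintentional = np.zeros(n, dtype=bool)

    k = espen_t.sum()
    wl6[espen_t] = np.minimum(
        th.glim_wl_moderate_6mo + 0.5 + rng.gamma(2.0, 2.5, k), 25.0
    )
    wl_beyond[espen_t] = np.where(
        rng.random(k) < 0.3, rng.uniform(10.5, 24.0, k), 0.0
    )
    unintentional[espen_t] = True

    fire_wl = glim_only & (rng.random(n) < 0.65)
    fire_mm = glim_only & (rng.random(n) < 0.75)
    neither = glim_only & ~fire_wl & ~fire_mm
    fire_mm |= neither
    k = fire_wl.sum()
    wl6[fire_wl] = np.minimum(
        th.glim_wl_moderate_6mo + 0.5 + rng.gamma(2.0, 2.0, k), 20.0
    )
    wl_beyond[fire_wl] = np.where(
        rng.random(k) < 0.2, rng.uniform(10.5, 22.0, k), 0.0
    )
    unintentional[fire_wl] = True
    quiet = glim_only & ~fire_wl
    k = quiet.sum()
    wl6[quiet] = np.where(
        rng.random(k) < 0.4, rng.uniform(0.0, th.glim_wl_moderate_6mo - 0.1, k), 0.0
    )
    unintentional[quiet] = rng.random(k) < 0.3

    k = clean_neg.sum()
    wl6[clean_neg] = np.where(
        rng.random(k) < 0.2, rng.uniform(0.0, th.glim_wl_moderate_6mo - 0.1, k), 0.0
    )
    k = pheno_only.sum()
    wl6[pheno_only] = np.where(
        rng.random(k) < 0.25, rng.uniform(5.5, 12.0, k), 0.0
    )
    wl6 = np.round(wl6, 1)
    wl_beyond = np.round(wl_beyond, 1)

    # -- muscle surrogates -------------------------------------------------
    calf_cut = np.where(male, th.calf_cutoff_male, th.calf_cutoff_female)
    grip_cut = np.where(male, th.grip_cutoff_male, th.grip_cutoff_female)
    fire_mm = fire_mm | (espen_t & (rng.random(n) < 0.8))
    mm_pheno = pheno_only & (rng.random(n) < 0.4)
    calf_low = (fire_mm | mm_pheno) & (rng.random(n) < 0.85)
    grip_low = (fire_mm | mm_pheno) & (rng.random(n) < 0.60)
    rescue = (fire_mm | mm_pheno) & ~calf_low & ~grip_low
    calf_low |= rescue

    calf = np.empty(n)
    m, s = cal.CALF_LOW
    calf[calf_low] = _tn(rng, m, s, 20.0, calf_cut[calf_low] - eps, calf_low.sum())
    m, s = cal.CALF_NORMAL
    hi_ok = ~calf_low
    calf[hi_ok] = _tn(rng, m, s, calf_cut[hi_ok], 46.0, hi_ok.sum())
    calf = np.round(calf, 1)

    grip = np.empty(n)
    for sel, (pm, pf) in (
        (grip_low, (cal.GRIP_LOW_MALE, cal.GRIP_LOW_FEMALE)),
        (~grip_low, (cal.GRIP_NORMAL_MALE, cal.GRIP_NORMAL_FEMALE)),
    ):
        for is_male, (m, s) in ((True, pm), (False, pf)):
            rows = sel & (male == is_male)
            lo = 1.0 if sel is grip_low else grip_cut[rows]
            hi = grip_cut[rows] - eps if sel is grip_low else 60.0
            grip[rows] = _tn(rng, m, s, lo, hi, rows.sum())
    grip = np.round(grip, 1)

    mid_arm = np.round(
        np.clip(
            np.where(
                glim_t,
                rng.normal(*cal.MID_ARM["mal"], n),
                rng.normal(*cal.MID_ARM["normal"], n),
            ),
            15.0,
            40.0,
        ),
        1,
    )

    # -- etiologic fields --------------------------------------------------
    albumin = np.empty(n)
    m, s = cal.LABS["albumin_g_L"][0]
    albumin[glim_t] = _tn(rng, m, s, 18.0, 55.0, glim_t.sum())
    m, s = cal.LABS["albumin_g_L"][1]
    albumin[clean_neg] = _tn(rng, m, s, 18.0, 55.0, clean_neg.sum())
    # phenotypic-only negatives must not meet the inflammation criterion
    albumin[pheno_only] = _tn(
        rng, m, s, th.albumin_inflammation, 55.0, pheno_only.sum()
    )
    albumin = np.round(albumin, 1)

    inflam_flag = np.zeros(n, dtype=bool)
    inflam_flag[glim_t] = rng.random(glim_t.sum()) < 0.30
    inflam_flag[clean_neg] = rng.random(clean_neg.sum()) < 0.12
    intake_50 = np.zeros(n, dtype=bool)
    intake_2wk = np.zeros(n, dtype=bool)
    chronic_gi = np.zeros(n, dtype=bool)
    intake_50[glim_t] = rng.random(glim_t.sum()) < 0.30
    intake_2wk[glim_t] = rng.random(glim_t.sum()) < 0.50
    chronic_gi[glim_t] = rng.random(glim_t.sum()) < 0.20
    intake_50[clean_neg] = rng.random(clean_neg.sum()) < 0.05
    intake_2wk[clean_neg] = rng.random(clean_neg.sum()) < 0.08
    chronic_gi[clean_neg] = rng.random(clean_neg.sum()) < 0.05
    # guarantee >= 1 etiologic criterion for the GLIM tier
    no_etio = glim_t & ~(
        intake_50 | intake_2wk | chronic_gi | inflam_flag
        | (albumin < th.albumin_inflammation)
    )
    intake_2wk[no_etio] = True

    # -- 8-item bedside assessment ----------------------------------------
    need = th.sga_items_required
    n_items = len(SGA_ITEM_NAMES)
    n_c = np.zeros(n, dtype=int)
    n_b = np.zeros(n, dtype=int)

    severe_t = sga_t & (rng.random(n) < cfg.sga_severe_frac)
    k = severe_t.sum()
    n_c[severe_t] = need + rng.binomial(n_items - need, 0.4, k)
    n_b[severe_t] = rng.binomial(n_items - n_c[severe_t], 0.5)
    moderate_t = sga_t & ~severe_t
    k = moderate_t.sum()
    total_bc = need + rng.binomial(n_items - need, 0.35, k)
    cc = np.minimum(rng.binomial(total_bc, 0.25), need - 1)
    n_c[moderate_t] = cc
    n_b[moderate_t] = total_bc - cc
    border = glim_t & ~sga_t
    k = border.sum()
    total_bc = rng.choice([2, 3, 4], size=k, p=[0.3, 0.4, 0.3])
    cc = rng.binomial(total_bc, 0.2)
    n_c[border] = cc
    n_b[border] = total_bc - cc
    k = neg.sum()
    total_bc = rng.choice([0, 1, 2], size=k, p=[0.5, 0.35, 0.15])
    cc = rng.binomial(total_bc, 0.1)
    n_c[neg] = cc
    n_b[neg] = total_bc - cc

    order = np.argsort(rng.random((n, n_items)), axis=1)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_items)[None, :].repeat(n, 0), axis=1)
    ratings = np.where(
        ranks < n_c[:, None], "C", np.where(ranks < (n_c + n_b)[:, None], "B", "A")
    )

    # -- descriptive labs --------------------------------------------------
    labs: dict[str, np.ndarray] = {}
    for name, ((m1, s1), (m0, s0)) in cal.LABS.items():
        if name == "albumin_g_L":
            continue
        vals = np.where(glim_t, rng.normal(m1, s1, n), rng.normal(m0, s0, n))
        labs[name] = np.round(np.clip(vals, 0.05 * m0, None), 2)
    for stratum, (med, qd) in (
        ("mal", cal.LYMPHOCYTES_MAL),
        ("normal", cal.LYMPHOCYTES_NORMAL),
    ):
        sigma = np.arcsinh(qd / med) / norm.ppf(0.75)
        sel = glim_t if stratum == "mal" else neg
        labs.setdefault("lymphocytes_1e9_L", np.empty(n))[sel] = rng.lognormal(
            np.log(med), sigma, sel.sum()
        )
    labs["lymphocytes_1e9_L"] = np.round(labs["lymphocytes_1e9_L"], 2)

    # -- outcomes ----------------------------------------------------------
    eta = (
        special.logit(cfg.baseline_complication_p)
        + np.log(cfg.or_glim) * glim_t
        + np.log(cfg.or_sga) * sga_t
        + np.log(cfg.or_espen) * espen_t
        + np.log(cfg.or_age_per_year) * (age - cfg.age_mean)
        + np.log(cfg.or_male) * (male - cfg.male_frac)
        + np.log(cfg.or_married) * (married - cfg.married_frac)
    )
    total_comp = rng.random(n) < special.expit(eta)
    infectious = total_comp & (rng.random(n) < cfg.infectious_frac)
    noninfectious = total_comp & ~infectious

    icu = rng.random(n) < cfg.icu_frac
    icu_days = np.where(icu, np.round(rng.lognormal(0.8, 0.6, n), 1), 0.0)
    mortality = rng.random(n) < np.where(glim_t, cfg.mortality_mal, cfg.mortality_normal)

    lo, hi = cfg.los_window
    los = np.empty(n)
    for sel, (m, s) in ((glim_t, cfg.los_mal), (neg, cfg.los_normal)):
        k = sel.sum()
        los[sel] = _rejection_window(
            lambda k=k, m=m, s=s: _lognormal_from_moments(rng, m, s, k), lo, hi
        )
    los = np.round(los, 1)
    expenses = np.round(
        np.where(
            glim_t,
            rng.lognormal(np.log(cal.EXPENSES_MEDIAN_MAL), cal.EXPENSES_SIGMA, n),
            rng.lognormal(np.log(cal.EXPENSES_MEDIAN_NORMAL), cal.EXPENSES_SIGMA, n),
        ),
        2,
    )

    # -- assemble ----------------------------------------------------------
    data = {
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "age": age,
        "sex": sex,
        "marital_status": np.where(married, "married", "other"),
        "education": education,
        "admission_reason": admission,
        "nrs2002_total": nrs,
        "height_cm": height,
        "weight_kg": weight,
        "bmi_kg_m2": np.round(bmi, 4),
        "weight_loss_pct_6mo": wl6,
        "weight_loss_pct_beyond_6mo": wl_beyond,
        "unintentional_weight_loss": unintentional,
        "calf_circumference_cm": calf,
        "grip_strength_kg": grip,
        "mid_arm_circumference_cm": mid_arm,
        "albumin_g_L": albumin,
        "hemoglobin_g_L": labs["hemoglobin_g_L"],
        "lymphocytes_1e9_L": labs["lymphocytes_1e9_L"],
        "total_protein_g_L": labs["total_protein_g_L"],
        "prealbumin_g_L": labs["prealbumin_g_L"],
        "triglyceride_mmol_L": labs["triglyceride_mmol_L"],
        "cholesterol_mmol_L": labs["cholesterol_mmol_L"],
        "intake_reduced_gt50pct_1wk": intake_50,
        "intake_reduced_gt2wk": intake_2wk,
        "chronic_gi_disease": chronic_gi,
        "inflammatory_condition": inflam_flag,
        "total_complication": total_comp,
        "infectious_complication": infectious,
        "noninfectious_complication": noninfectious,
        "icu_admission": icu,
        "icu_days": icu_days,
        "mortality": mortality,
        "los_days": los,
        "expenses_usd": expenses,
    }
    for name, col in zip(SGA_ITEM_NAMES, ratings.T):
        data[f"sga_{name}"] = col
    cohort = pd.DataFrame(data)[list(CANONICAL_COLUMNS)]

    # -- engine-verified report -------------------------------------------
    dx = diagnose_all(cohort, th)
    g = dx["glim_status"].to_numpy()
    comp = cohort["total_complication"].to_numpy(dtype=bool)
    report = GenerationReport(
        n=n,
        seed=cfg.seed,
        prevalence_glim=float(g.mean()),
        prevalence_sga=float(dx["sga_status"].mean()),
        prevalence_espen=float(dx["espen_status"].mean()),
        nesting_violations_sga_glim=int((dx["sga_status"] & ~dx["glim_status"]).sum()),
        nesting_violations_espen_glim=int(
            (dx["espen_status"] & ~dx["glim_status"]).sum()
        ),
        gate_violations=int(
            ((dx["glim_status"] | dx["espen_status"]) & ~dx["nrs_at_risk"]).sum()
        ),
        complication_incidence_glim_pos=float(comp[g].mean()) if g.any() else float("nan"),
        complication_incidence_glim_neg=float(comp[~g].mean()) if (~g).any() else float("nan"),
    )
    return cohort, report


# ---------------------------------------------------------------------------
# Published-marginal concordance fixtures
# ---------------------------------------------------------------------------

def generate_confusion_fixtures() -> dict[str, ConfusionTable2x2]:
    """The three cross-criteria 2x2 tables implied by the published
    marginal counts of the reference cohort (n = 2526; 956 GLIM+, 829
    SGA+, 429 ESPEN+) together with its printed 100% sensitivities and
    specificities. Cell order: (test+ref+, test+ref-, test-ref+, test-ref-).
    """
    return {
        "GLIM_vs_SGA": ConfusionTable2x2(829, 127, 0, 1570, label="GLIM vs SGA"),
        "GLIM_vs_ESPEN": ConfusionTable2x2(429, 527, 0, 1570, label="GLIM vs ESPEN 2015"),
        "ESPEN_vs_SGA": ConfusionTable2x2(429, 0, 400, 1697, label="ESPEN 2015 vs SGA"),
    }


# ---------------------------------------------------------------------------
# Importance experiments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImportanceEffectSpec:
    """Planted outcome effects for feature-importance experiments.

    The log-odds increments are cumulative over the nested tiers, so the
    marginal risk jump at the GLIM boundary must dominate for the GLIM
    indicator to carry the strongest signal; the defaults encode a strictly
    ordered GLIM > SGA > ESPEN effect with a baseline raised enough for the
    rare-outcome classifier to learn from.
    """

    or_glim: float = 4.0
    or_sga: float = 1.2
    or_espen: float = 1.1
    baseline_p: float = 0.08


def plant_importance_structure(
    config: CohortConfig = CohortConfig(),
    effects: ImportanceEffectSpec = ImportanceEffectSpec(),
) -> CohortConfig:
    """Config whose outcome model loads strictly ordered effects on the
    GLIM / SGA / ESPEN indicators (strongest first).

    A zero-effect spec (all ORs = 1) is allowed for null experiments; any
    other non-strictly-ordered spec is rejected as inconsistent.
    """
    lg, ls, le = (
        np.log(effects.or_glim),
        np.log(effects.or_sga),
        np.log(effects.or_espen),
    )
    if not (lg == ls == le == 0.0):
        if not (lg > ls > le >= 0.0):
            raise ValueError(
                "inconsistent effect ordering: require OR_GLIM > OR_SGA > "
                f"OR_ESPEN >= 1 (got {effects.or_glim}, {effects.or_sga}, "
                f"{effects.or_espen})"
            )
    return config.model_copy(
        update={
            "or_glim": effects.or_glim,
            "or_sga": effects.or_sga,
            "or_espen": effects.or_espen,
            "baseline_complication_p": effects.baseline_p,
        }
    )
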