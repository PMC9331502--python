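"""Rule-based malnutrition classifiers: GLIM, SGA and ESPEN 2015.

Three engines share one convention set:

* **Screening gate.** GLIM and ESPEN 2015 diagnose only patients at
  nutritional risk on NRS-2002 (total score >= 3); the 8-item subjective
  global assessment has no screening step.
* **GLIM.** Malnourished iff at least one phenotypic criterion (weight
  loss, low BMI, low muscle mass via calf-circumference or grip-strength
  surrogates) **and** at least one etiologic criterion (reduced intake /
  impaired absorption, inflammation via disease burden or albumin < 35 g/L)
  fire. Severity: severe on >10% weight loss within 6 months, >20% beyond
  6 months, or BMI below the age-specific severe cutoff; else moderate.
* **SGA.** Malnourished iff at least 5 of the 8 items rate B or C; severe
  iff at least 5 rate C (pluggable rule — the moderate/severe boundary is
  a bedside convention, not part of the published scale).
* **ESPEN 2015.** Malnourished iff BMI < 18.5 kg/m^2, or unintentional
  weight loss combined with age-adjusted BMI (< 20 for age < 70, < 22 for
  age >= 70).

All threshold comparisons are strict exactly as printed: BMI 18.5 does not
fire "BMI < 18.5", albumin 35 does not fire "< 35 g/L", NRS 3 does pass
">= 3". Missing inputs are governed by a policy: under ``"lenient"`` a rule
with missing inputs simply cannot fire; under ``"strict"`` missing
mandatory inputs raise (scalar API) or mark the record unevaluable
(cohort API).

Scalar functions (one record at a time, returning rich
:class:`DiagnosisResult` objects) are the reference implementation;
:func:`diagnose_all` is an equivalent vectorized path for whole cohorts,
property-tested against the scalar one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import SGA_ITEM_NAMES, PatientRecord, SGAItems
from .thresholds import CriteriaThresholds

Policy = Literal["strict", "lenient"]
MuscleRule = Literal["or", "and"]
Criterion = Literal["GLIM", "SGA", "ESPEN2015"]

DEFAULT_THRESHOLDS = CriteriaThresholds()


class MissingDataError(Exception):
    """Mandatory input absent under the strict missing-data policy."""


@dataclass
class DiagnosisResult:
    """Per-criterion verdict for one patient."""

    criterion: Criterion
    status: Literal["malnourished", "not_malnourished"]
    severity: Literal["none", "moderate", "severe"] = "none"
    screening_passed: Optional[bool] = None  # None: criterion has no gate
    triggered_rules: list[str] = field(default_factory=list)
    evaluable: bool = True

    @property
    def malnourished(self) -> bool:
        return self.status == "malnourished"


def _value(record, name: str):
    """Missing-safe attribute access (None and NaN both mean missing)."""
    v = getattr(record, name, None)
    if v is None:
        return None
    if isinstance(v, float) and math.isnan(v):
        return None
    return v


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

def screen_nrs(
    record,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    policy: Policy = "strict",
) -> bool:
    """NRS-2002 nutritional-risk gate: True iff total score >= cutoff."""
    score = _value(record, "nrs2002_total")
    if score is None:
        if policy == "strict":
            raise MissingDataError("nrs2002_total is missing")
        return False
    return score >= thresholds.nrs_cutoff


# ---------------------------------------------------------------------------
# SGA
# ---------------------------------------------------------------------------

def _sga_ratings(items) -> dict[str, Optional[str]]:
    if isinstance(items, SGAItems):
        return dict(items.ratings())
    if isinstance(items, Mapping):
        return {name: items.get(name) for name in SGA_ITEM_NAMES}
    if isinstance(items, Sequence) and not isinstance(items, str):
        if len(items) != len(SGA_ITEM_NAMES):
            raise ValueError(f"expected {len(SGA_ITEM_NAMES)} item ratings")
        return dict(zip(SGA_ITEM_NAMES, items))
    raise TypeError(f"cannot interpret SGA items from {type(items)!r}")


def diagnose_sga(
    items: Union[SGAItems, Mapping[str, str], Sequence[str]],
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    policy: Policy = "strict",
    severe_rule: Literal["c_count", "all"] = "c_count",
) -> DiagnosisResult:
    """Classify from the eight A/B/C items.

    Malnourished iff >= ``sga_items_required`` items rate B or C. Severity
    under the default ``"c_count"`` rule: severe iff >= the same number of
    items rate C, else moderate.
    """
    ratings = _sga_ratings(items)
    missing = [k for k, v in ratings.items() if v is None]
    bad = [k for k, v in ratings.items() if v is not None and v not in ("A", "B", "C")]
    if bad:
        raise ValueError(f"invalid rating (not A/B/C) for item(s): {bad}")
    if missing and policy == "strict":
        raise MissingDataError(f"missing SGA item(s): {missing}")

    flagged = [k for k, v in ratings.items() if v in ("B", "C")]
    n_bc = len(flagged)
    n_c = sum(1 for v in ratings.values() if v == "C")
    need = thresholds.sga_items_required
    malnourished = n_bc >= need
    severity = "none"
    if malnourished:
        severity = "severe" if n_c >= need else "moderate"
    return DiagnosisResult(
        criterion="SGA",
        status="malnourished" if malnourished else "not_malnourished",
        severity=severity,
        screening_passed=None,
        triggered_rules=[f"sga.item.{k}:{ratings[k]}" for k in flagged],
        evaluable=not missing,
    )


# ---------------------------------------------------------------------------
# ESPEN 2015
# ---------------------------------------------------------------------------

def diagnose_espen(
    record,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    policy: Policy = "lenient",
) -> DiagnosisResult:
    """Two-step ESPEN 2015 classification (screen, then BMI routes)."""
    gate = screen_nrs(record, thresholds, policy)
    age = _value(record, "age")
    bmi = _value(record, "bmi_kg_m2")
    if (age is None or bmi is None) and policy == "strict":
        raise MissingDataError("age and bmi_kg_m2 are mandatory for ESPEN 2015")
    evaluable = age is not None and bmi is not None and _value(
        record, "nrs2002_total"
    ) is not None

    rules: list[str] = []
    if gate and bmi is not None:
        if bmi < thresholds.espen_bmi_abs:
            rules.append("espen.low_bmi_absolute")
        unintentional = _value(record, "unintentional_weight_loss")
        if (
            unintentional
            and age is not None
            and bmi < thresholds.espen_bmi_cutoff(age)
        ):
            rules.append("espen.weight_loss_age_bmi")
    malnourished = bool(rules)
    return DiagnosisResult(
        criterion="ESPEN2015",
        status="malnourished" if malnourished else "not_malnourished",
        severity="none",  # the 2015 consensus does not grade severity
        screening_passed=gate,
        triggered_rules=rules,
        evaluable=evaluable,
    )


# ---------------------------------------------------------------------------
# GLIM
# ---------------------------------------------------------------------------

def glim_phenotypic(
    record,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    muscle_rule: MuscleRule = "or",
) -> set[str]:
    """Fired phenotypic rule ids among weight_loss / low_bmi / low_muscle_mass."""
    fired: set[str] = set()
    wl6 = _value(record, "weight_loss_pct_6mo")
    wl_beyond = _value(record, "weight_loss_pct_beyond_6mo")
    if (wl6 is not None and wl6 > thresholds.glim_wl_moderate_6mo) or (
        wl_beyond is not None and wl_beyond > thresholds.glim_wl_moderate_beyond
    ):
        fired.add("glim.phenotypic.weight_loss")

    age = _value(record, "age")
    bmi = _value(record, "bmi_kg_m2")
    if age is not None and bmi is not None and bmi < thresholds.glim_bmi_cutoff(age):
        fired.add("glim.phenotypic.low_bmi")

    sex = _value(record, "sex")
    if sex is not None:
        calf = _value(record, "calf_circumference_cm")
        grip = _value(record, "grip_strength_kg")
        calf_low = calf is not None and calf < thresholds.calf_cutoff(sex)
        grip_low = grip is not None and grip < thresholds.grip_cutoff(sex)
        if muscle_rule == "or":
            muscle = calf_low or grip_low
        else:
            muscle = calf_low and grip_low
        if muscle:
            fired.add("glim.phenotypic.low_muscle_mass")
    return fired


def glim_etiologic(
    record, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> set[str]:
    """Fired etiologic rule ids among reduced_intake / inflammation."""
    fired: set[str] = set()
    if (
        _value(record, "intake_reduced_gt50pct_1wk")
        or _value(record, "intake_reduced_gt2wk")
        or _value(record, "chronic_gi_disease")
    ):
        fired.add("glim.etiologic.reduced_intake")
    albumin = _value(record, "albumin_g_L")
    if _value(record, "inflammatory_condition") or (
        albumin is not None and albumin < thresholds.albumin_inflammation
    ):
        fired.add("glim.etiologic.inflammation")
    return fired


def glim_severity(
    record, thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS
) -> Literal["moderate", "severe"]:
    """Severity grade for a patient already GLIM-malnourished."""
    wl6 = _value(record, "weight_loss_pct_6mo")
    wl_beyond = _value(record, "weight_loss_pct_beyond_6mo")
    if wl6 is not None and wl6 > thresholds.glim_wl_severe_6mo:
        return "severe"
    if wl_beyond is not None and wl_beyond > thresholds.glim_wl_severe_beyond:
        return "severe"
    age = _value(record, "age")
    bmi = _value(record, "bmi_kg_m2")
    if (
        age is not None
        and bmi is not None
        and bmi < thresholds.glim_severe_bmi_cutoff(age)
    ):
        return "severe"
    return "moderate"


def diagnose_glim(
    record,
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    policy: Policy = "lenient",
    muscle_rule: MuscleRule = "or",
) -> DiagnosisResult:
    """Full GLIM verdict: screen, phenotypic AND etiologic, severity."""
    gate = screen_nrs(record, thresholds, policy)
    evaluable = (
        _value(record, "nrs2002_total") is not None
        and _value(record, "age") is not None
        and _value(record, "bmi_kg_m2") is not None
    )
    if policy == "strict" and not evaluable:
        raise MissingDataError("nrs2002_total, age and bmi_kg_m2 are mandatory for GLIM")
    rules: list[str] = []
    malnourished = False
    severity: str = "none"
    if gate:
        phenotypic = glim_phenotypic(record, thresholds, muscle_rule)
        etiologic = glim_etiologic(record, thresholds)
        if phenotypic and etiologic:
            malnourished = True
            rules = sorted(phenotypic | etiologic)
            severity = glim_severity(record, thresholds)
    return DiagnosisResult(
        criterion="GLIM",
        status="malnourished" if malnourished else "not_malnourished",
        severity=severity,
        screening_passed=gate,
        triggered_rules=rules,
        evaluable=evaluable,
    )


# ---------------------------------------------------------------------------
# Cohort-level (vectorized) diagnosis
# ---------------------------------------------------------------------------

def _bool_col(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        return np.zeros(len(df), dtype=bool)
    col = df[name]
    return col.map(lambda v: bool(v) if v is not None and not pd.isna(v) else False).to_numpy(
        dtype=bool
    )


def _float_col(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        return np.full(len(df), np.nan)
    return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)


def diagnose_all(
    cohort: Union[pd.DataFrame, Sequence[PatientRecord]],
    thresholds: CriteriaThresholds = DEFAULT_THRESHOLDS,
    policy: Policy = "lenient",
    muscle_rule: MuscleRule = "or",
    severe_rule: Literal["c_count", "all"] = "c_count",
) -> pd.DataFrame:
    """Classify a whole cohort under all three criteria at once.

    Accepts the canonical cohort DataFrame (see :mod:`malnutdx.io`) or a
    list of records. Returns one row per patient with boolean status
    columns (``glim_status``, ``sga_status``, ``espen_status``), severity
    grades, the screening flag, per-rule boolean columns and an
    ``evaluable`` flag (False where NRS, age or BMI is missing). Under the
    strict policy unevaluable records raise :class:`MissingDataError`.
    """
    if not isinstance(cohort, pd.DataFrame):
        from .io import records_to_frame

        cohort = records_to_frame(list(cohort))
    n = len(cohort)
    with np.errstate(invalid="ignore"):
        age = _float_col(cohort, "age")
        bmi = _float_col(cohort, "bmi_kg_m2")
        nrs = _float_col(cohort, "nrs2002_total")
        old = age >= thresholds.age_pivot

        at_risk = nrs >= thresholds.nrs_cutoff
        evaluable = ~np.isnan(nrs) & ~np.isnan(age) & ~np.isnan(bmi)
        if policy == "strict" and not evaluable.all():
            raise MissingDataError(
                f"{int((~evaluable).sum())} record(s) missing NRS, age or BMI"
            )

        # GLIM phenotypic
        wl6 = _float_col(cohort, "weight_loss_pct_6mo")
        wlb = _float_col(cohort, "weight_loss_pct_beyond_6mo")
        r_weight_loss = (wl6 > thresholds.glim_wl_moderate_6mo) | (
            wlb > thresholds.glim_wl_moderate_beyond
        )
        glim_bmi_cut = np.where(old, thresholds.glim_bmi_old, thresholds.glim_bmi_young)
        r_low_bmi = bmi < glim_bmi_cut

        male = cohort["sex"].astype(str).to_numpy() == "male"
        calf = _float_col(cohort, "calf_circumference_cm")
        grip = _float_col(cohort, "grip_strength_kg")
        calf_low = calf < np.where(
            male, thresholds.calf_cutoff_male, thresholds.calf_cutoff_female
        )
        grip_low = grip < np.where(
            male, thresholds.grip_cutoff_male, thresholds.grip_cutoff_female
        )
        r_muscle = calf_low | grip_low if muscle_rule == "or" else calf_low & grip_low
        phenotypic = r_weight_loss | r_low_bmi | r_muscle

        # GLIM etiologic
        r_intake = (
            _bool_col(cohort, "intake_reduced_gt50pct_1wk")
            | _bool_col(cohort, "intake_reduced_gt2wk")
            | _bool_col(cohort, "chronic_gi_disease")
        )
        albumin = _float_col(cohort, "albumin_g_L")
        r_inflammation = _bool_col(cohort, "inflammatory_condition") | (
            albumin < thresholds.albumin_inflammation
        )
        etiologic = r_intake | r_inflammation

        glim_status = at_risk & phenotypic & etiologic
        severe_bmi_cut = np.where(
            old, thresholds.glim_severe_bmi_old, thresholds.glim_severe_bmi_young
        )
        glim_severe = glim_status & (
            (wl6 > thresholds.glim_wl_severe_6mo)
            | (wlb > thresholds.glim_wl_severe_beyond)
            | (bmi < severe_bmi_cut)
        )
        glim_severity_col = np.where(
            glim_status, np.where(glim_severe, "severe", "moderate"), "none"
        )

        # ESPEN 2015
        unintentional = _bool_col(cohort, "unintentional_weight_loss")
        espen_cut = np.where(old, thresholds.espen_bmi_old, thresholds.espen_bmi_young)
        espen_status = at_risk & (
            (bmi < thresholds.espen_bmi_abs) | (unintentional & (bmi < espen_cut))
        )

        # SGA
        sga_cols = [f"sga_{name}" for name in SGA_ITEM_NAMES]
        if all(c in cohort.columns for c in sga_cols):
            ratings = cohort[sga_cols].astype("string")
            n_bc = ratings.isin(["B", "C"]).sum(axis=1).to_numpy()
            n_c = (ratings == "C").sum(axis=1).to_numpy()
            need = thresholds.sga_items_required
            sga_status = n_bc >= need
            sga_severity_col = np.where(
                sga_status, np.where(n_c >= need, "severe", "moderate"), "none"
            )
        else:
            sga_status = np.zeros(n, dtype=bool)
            sga_severity_col = np.full(n, "none")

    return pd.DataFrame(
        {
            "patient_id": cohort.get("patient_id", pd.Series(range(n))).to_numpy(),
            "nrs_at_risk": at_risk,
            "glim_status": glim_status,
            "glim_severity": glim_severity_col,
            "sga_status": sga_status,
            "sga_severity": sga_severity_col,
            "espen_status": espen_status,
            "glim_rule_weight_loss": glim_status & r_weight_loss,
            "glim_rule_low_bmi": glim_status & r_low_bmi,
            "glim_rule_low_muscle_mass": glim_status & r_muscle,
            "glim_rule_reduced_intake": glim_status & r_intake,
            "glim_rule_inflammation": glim_status & r_inflammation,
            "evaluable": evaluable,
        }
    )


def prevalence_summary(dx: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per criterion and severity stratum.

    Percentages are NaN on an empty table rather than raising.
    """
    n = len(dx)
    rows = []
    for criterion, status_col, sev_col in (
        ("GLIM", "glim_status", "glim_severity"),
        ("SGA", "sga_status", "sga_severity"),
        ("ESPEN2015", "espen_status", None),
    ):
        count = int(dx[status_col].sum()) if n else 0
        rows.append(
            {
                "criterion": criterion,
                "stratum": "malnourished",
                "count": count,
                "percent": 100.0 * count / n if n else float("nan"),
            }
        )
        if sev_col is not None:
            for sev in ("moderate", "severe"):
                c = int((dx[sev_col] == sev).sum()) if n else 0
                rows.append(
                    {
                        "criterion": criterion,
                        "stratum": sev,
                        "count": c,
                        "percent": 100.0 * c / n if n else float("nan"),
                    }
                )
    return pd.DataFrame(rows)
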