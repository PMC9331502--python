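"""Typed patient-level data model for elderly-inpatient malnutrition cohorts.

A :class:`PatientRecord` carries everything the three diagnostic engines and
the outcome analyses consume: demographics, anthropometrics, laboratory
values, the NRS-2002 screening total, weight-loss and intake-reduction
fields, disease-burden flags, the eight A/B/C-rated bedside assessment items
and the in-hospital outcome panel.

Missing clinical values are represented as ``None`` (never 0): the rule
engines must be able to distinguish "grip strength not measured" from
"grip strength 0 kg".
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

Sex = Literal["male", "female"]
MaritalStatus = Literal["married", "other"]
Education = Literal["primary_or_lower", "high_school", "bachelor_or_above"]
AdmissionReason = Literal[
    "tumor",
    "digestive",
    "nervous",
    "respiratory",
    "cardiovascular",
    "osteoarthropathy",
    "endocrine",
    "kidney",
    "other",
]
SGARating = Literal["A", "B", "C"]

#: Canonical order of the eight bedside assessment items.
SGA_ITEM_NAMES = (
    "weight_change",
    "intake_change",
    "gi_symptoms",
    "physical_activity",
    "disease_nutritional_demand",
    "subcutaneous_fat_loss",
    "muscle_atrophy",
    "ankle_edema",
)


class SGAItems(BaseModel):
    """The eight A/B/C item ratings of the subjective global assessment.

    Ratings are ordered A < B < C by severity; A is the normal finding.
    """

    model_config = ConfigDict(frozen=True)

    weight_change: SGARating
    intake_change: SGARating
    gi_symptoms: SGARating
    physical_activity: SGARating
    disease_nutritional_demand: SGARating
    subcutaneous_fat_loss: SGARating
    muscle_atrophy: SGARating
    ankle_edema: SGARating

    def ratings(self) -> dict[str, SGARating]:
        """Item-name → rating mapping in canonical item order."""
        return {name: getattr(self, name) for name in SGA_ITEM_NAMES}


class OutcomePanel(BaseModel):
    """In-hospital outcomes recorded within 30 days of admission."""

    model_config = ConfigDict(frozen=True)

    total_complication: bool = False
    infectious_complication: bool = False
    noninfectious_complication: bool = False
    icu_admission: bool = False
    icu_days: float = Field(default=0.0, ge=0)
    mortality: bool = False
    los_days: Optional[float] = Field(default=None, ge=0)
    expenses_usd: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _check_consistency(self) -> "OutcomePanel":
        if self.total_complication != (
            self.infectious_complication or self.noninfectious_complication
        ):
            raise ValueError(
                "total_complication must equal infectious OR noninfectious"
            )
        if self.icu_days > 0 and not self.icu_admission:
            raise ValueError("icu_days > 0 requires icu_admission")
        return self


class PatientRecord(BaseModel):
    """One inpatient: demographics, anthropometrics, labs, criterion inputs.

    ``bmi_kg_m2`` is derived from weight and height when not supplied.
    Optional clinical fields default to ``None`` ("not recorded").
    """

    model_config = ConfigDict(frozen=False, validate_assignment=True)

    patient_id: str
    age: float = Field(ge=18)
    sex: Sex
    marital_status: MaritalStatus = "married"
    education: Education = "primary_or_lower"
    admission_reason: AdmissionReason = "other"
    nrs2002_total: Optional[int] = Field(default=None, ge=0, le=7)

    height_cm: Optional[float] = Field(default=None, gt=0)
    weight_kg: Optional[float] = Field(default=None, gt=0)
    bmi_kg_m2: Optional[float] = Field(default=None, gt=0)

    weight_loss_pct_6mo: Optional[float] = Field(default=None, ge=0)
    weight_loss_pct_beyond_6mo: Optional[float] = Field(default=None, ge=0)
    unintentional_weight_loss: Optional[bool] = None

    calf_circumference_cm: Optional[float] = Field(default=None, gt=0)
    grip_strength_kg: Optional[float] = Field(default=None, ge=0)
    mid_arm_circumference_cm: Optional[float] = Field(default=None, gt=0)

    albumin_g_L: Optional[float] = None
    hemoglobin_g_L: Optional[float] = None
    lymphocytes_1e9_L: Optional[float] = None
    total_protein_g_L: Optional[float] = None
    prealbumin_g_L: Optional[float] = None
    triglyceride_mmol_L: Optional[float] = None
    cholesterol_mmol_L: Optional[float] = None

    intake_reduced_gt50pct_1wk: Optional[bool] = None
    intake_reduced_gt2wk: Optional[bool] = None
    chronic_gi_disease: Optional[bool] = None
    inflammatory_condition: Optional[bool] = None

    sga_items: Optional[SGAItems] = None
    outcomes: Optional[OutcomePanel] = None

    #: Unknown extra input columns, passed through untouched on round trips.
    extras: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _derive_bmi(self) -> "PatientRecord":
        if self.bmi_kg_m2 is None and self.height_cm and self.weight_kg:
            derived = self.weight_kg / (self.height_cm / 100.0) ** 2
            object.__setattr__(self, "bmi_kg_m2", derived)
        return self

    def derived_bmi(self) -> Optional[float]:
        """BMI recomputed from weight and height, or None if either missing."""
        if self.height_cm and self.weight_kg:
            return self.weight_kg / (self.height_cm / 100.0) ** 2
        return None

    def bmi_discrepancy(self) -> Optional[float]:
        """Absolute difference between recorded and derived BMI (kg/m^2)."""
        derived = self.derived_bmi()
        if derived is None or self.bmi_kg_m2 is None:
            return None
        return abs(self.bmi_kg_m2 - derived)


def validate_records(
    records: list[PatientRecord], bmi_flag_threshold: float = 0.5
) -> list[str]:
    """Cross-field validation log for an already-parsed cohort.

    Currently flags recorded-vs-derived BMI disagreement above
    ``bmi_flag_threshold`` kg/m^2; parse-time domain violations are raised
    eagerly by the record model itself.
    """
    issues: list[str] = []
    for rec in records:
        disc = rec.bmi_discrepancy()
        if disc is not None and disc > bmi_flag_threshold and not math.isnan(disc):
            issues.append(
                f"patient {rec.patient_id}: recorded BMI {rec.bmi_kg_m2:.2f} "
                f"differs from derived {rec.derived_bmi():.2f} by {disc:.2f} kg/m^2"
            )
    return issues
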