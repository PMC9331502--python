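"""Clinical cutoffs used by the three diagnostic engines.

All thresholds are exact clinical conventions at the printed precision:
comparisons in the engines are strict (`BMI < 18.5` does not fire at
exactly 18.5; `NRS >= 3` does pass at exactly 3). Units are fixed
(kg/m^2, cm, kg, g/L, percent, years); no automatic conversion is done.

Defaults follow the Asian GLIM BMI cutoffs, AWGS 2019 muscle-surrogate
cutoffs (calf circumference < 34/33 cm, grip strength < 28/18 kg for
men/women), the ESPEN 2015 age-adjusted BMI route, an NRS-2002 risk cutoff
of 3 and serum albumin < 35 g/L as the inflammation surrogate. Every value
can be overridden from a YAML/JSON file whose keys mirror the field names.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml


@dataclass(frozen=True)
class CriteriaThresholds:
    # Screening
    nrs_cutoff: int = 3
    # Age pivot separating the "young elderly" cutoffs from the >= 70 y ones
    age_pivot: float = 70.0
    # GLIM phenotypic: low BMI (Asian cutoffs)
    glim_bmi_young: float = 18.5
    glim_bmi_old: float = 20.0
    # GLIM severity BMI cutoffs
    glim_severe_bmi_young: float = 17.8
    glim_severe_bmi_old: float = 17.0
    # GLIM weight loss, percent of body weight
    glim_wl_moderate_6mo: float = 5.0
    glim_wl_moderate_beyond: float = 10.0
    glim_wl_severe_6mo: float = 10.0
    glim_wl_severe_beyond: float = 20.0
    # Muscle-mass surrogates (AWGS 2019)
    calf_cutoff_male: float = 34.0
    calf_cutoff_female: float = 33.0
    grip_cutoff_male: float = 28.0
    grip_cutoff_female: float = 18.0
    # Inflammation surrogate
    albumin_inflammation: float = 35.0
    # ESPEN 2015
    espen_bmi_abs: float = 18.5
    espen_bmi_young: float = 20.0
    espen_bmi_old: float = 22.0
    # Bedside 8-item scale
    sga_items_required: int = 5

    def __post_init__(self) -> None:
        for field in dataclasses.fields(self):
            if float(getattr(self, field.name)) <= 0:
                raise ValueError(f"threshold {field.name} must be strictly positive")

    # -- age-dependent lookups -------------------------------------------
    def glim_bmi_cutoff(self, age: float) -> float:
        return self.glim_bmi_young if age < self.age_pivot else self.glim_bmi_old

    def glim_severe_bmi_cutoff(self, age: float) -> float:
        return (
            self.glim_severe_bmi_young
            if age < self.age_pivot
            else self.glim_severe_bmi_old
        )

    def espen_bmi_cutoff(self, age: float) -> float:
        return self.espen_bmi_young if age < self.age_pivot else self.espen_bmi_old

    def calf_cutoff(self, sex: str) -> float:
        return self.calf_cutoff_male if sex == "male" else self.calf_cutoff_female

    def grip_cutoff(self, sex: str) -> float:
        return self.grip_cutoff_male if sex == "male" else self.grip_cutoff_female

    # -- overrides --------------------------------------------------------
    def replace(self, **overrides: float) -> "CriteriaThresholds":
        return dataclasses.replace(self, **overrides)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "CriteriaThresholds":
        """Load overrides from a YAML or JSON mapping of field names."""
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ValueError(f"thresholds file {path} must contain a mapping")
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown threshold name(s): {sorted(unknown)}")
        return cls(**data)
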