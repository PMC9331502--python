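import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from malnutdx.records import OutcomePanel, PatientRecord, SGAItems
from malnutdx.synthetic import CohortConfig, generate_cohort
from malnutdx.thresholds import CriteriaThresholds

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def thresholds() -> CriteriaThresholds:
    return CriteriaThresholds()


@pytest.fixture
def patient() -> PatientRecord:
    """A GLIM-malnourished worked example: at risk, low BMI, low albumin."""
    return PatientRecord(
        patient_id="P1",
        age=75,
        sex="female",
        nrs2002_total=3,
        height_cm=160,
        weight_kg=48.6,
        albumin_g_L=33.0,
    )


@pytest.fixture
def all_a_items() -> SGAItems:
    return SGAItems(**{k: "A" for k in SGAItems.model_fields})


@pytest.fixture(scope="session")
def default_cohort() -> tuple[pd.DataFrame, object]:
    """One default-config synthetic cohort, shared across tests."""
    return generate_cohort(CohortConfig(seed=20240901))


@pytest.fixture
def small_records() -> list[PatientRecord]:
    return [
        PatientRecord(
            patient_id="A",
            age=75,
            sex="male",
            nrs2002_total=4,
            height_cm=170,
            weight_kg=55,
            albumin_g_L=31,
            calf_circumference_cm=31,
            grip_strength_kg=20,
            outcomes=OutcomePanel(los_days=12.0),
        ),
        PatientRecord(
            patient_id="B",
            age=68,
            sex="female",
            nrs2002_total=1,
            height_cm=158,
            weight_kg=60,
        ),
        PatientRecord(
            patient_id="C",
            age=82,
            sex="female",
            nrs2002_total=5,
            height_cm=150,
            weight_kg=39,
            unintentional_weight_loss=True,
            weight_loss_pct_6mo=12.0,
            intake_reduced_gt2wk=True,
            sga_items=SGAItems(
                weight_change="C",
                intake_change="C",
                gi_symptoms="B",
                physical_activity="B",
                disease_nutritional_demand="B",
                subcutaneous_fat_loss="A",
                muscle_atrophy="A",
                ankle_edema="A",
            ),
        ),
    ]


def random_record_frame(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Unconstrained random cohort rows (with missingness) for property tests."""

    def maybe(values, p=0.15):
        values = np.asarray(values, dtype=float)
        values[rng.random(n) < p] = np.nan
        return values

    df = pd.DataFrame(
        {
            "patient_id": [f"R{i}" for i in range(n)],
            "age": rng.uniform(65, 95, n).round(1),
            "sex": rng.choice(["male", "female"], n),
            "marital_status": rng.choice(["married", "other"], n),
            "nrs2002_total": rng.integers(0, 8, n),
            "bmi_kg_m2": maybe(rng.uniform(14, 35, n)),
            "weight_loss_pct_6mo": maybe(rng.uniform(0, 25, n)),
            "weight_loss_pct_beyond_6mo": maybe(rng.uniform(0, 30, n)),
            "unintentional_weight_loss": rng.random(n) < 0.4,
            "calf_circumference_cm": maybe(rng.uniform(22, 42, n)),
            "grip_strength_kg": maybe(rng.uniform(5, 50, n)),
            "albumin_g_L": maybe(rng.uniform(20, 50, n)),
            "intake_reduced_gt50pct_1wk": rng.random(n) < 0.2,
            "intake_reduced_gt2wk": rng.random(n) < 0.3,
            "chronic_gi_disease": rng.random(n) < 0.15,
            "inflammatory_condition": rng.random(n) < 0.2,
        }
    )
    for i, name in enumerate(
        [
            "sga_weight_change",
            "sga_intake_change",
            "sga_gi_symptoms",
            "sga_physical_activity",
            "sga_disease_nutritional_demand",
            "sga_subcutaneous_fat_loss",
            "sga_muscle_atrophy",
            "sga_ankle_edema",
        ]
    ):
        df[name] = rng.choice(["A", "B", "C"], n)
    return df
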