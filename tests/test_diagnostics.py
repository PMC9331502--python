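"""Rule-engine behaviour: worked examples, oracles and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from malnutdx.diagnostics import (
    MissingDataError,
    diagnose_all,
    diagnose_espen,
    diagnose_glim,
    diagnose_sga,
    glim_etiologic,
    glim_phenotypic,
    glim_severity,
    prevalence_summary,
    screen_nrs,
)
from malnutdx.records import SGA_ITEM_NAMES, PatientRecord
from malnutdx.thresholds import CriteriaThresholds

from conftest import random_record_frame


def make(**kw) -> PatientRecord:
    base = dict(patient_id="T", age=75, sex="male")
    base.update(kw)
    return PatientRecord(**base)


class TestScreening:
    @pytest.mark.parametrize("nrs,expected", [(3, True), (2, False), (7, True), (0, False)])
    def test_cutoff(self, nrs, expected):
        assert screen_nrs(make(nrs2002_total=nrs)) is expected

    def test_missing_score_strict_vs_lenient(self):
        rec = make()
        with pytest.raises(MissingDataError):
            screen_nrs(rec, policy="strict")
        assert screen_nrs(rec, policy="lenient") is False


class TestSGA:
    @pytest.mark.parametrize(
        "ratings,status,severity",
        [
            ("BBBBBAAA", "malnourished", "moderate"),
            ("AAAAAAAA", "not_malnourished", "none"),
            ("CCCCCAAA", "malnourished", "severe"),
            ("BBBBAAAA", "not_malnourished", "none"),  # 4 of 8 is below the bar
            ("CCCCBBBB", "malnourished", "moderate"),  # only 4 C ratings
            ("CCCCCCCC", "malnourished", "severe"),
        ],
    )
    def test_worked_examples(self, ratings, status, severity):
        result = diagnose_sga(list(ratings))
        assert result.status == status
        assert result.severity == severity

    def test_triggered_rules_list_flagged_items(self):
        result = diagnose_sga(list("BCAAAABB"))
        assert sorted(result.triggered_rules) == sorted(
            [
                "sga.item.weight_change:B",
                "sga.item.intake_change:C",
                "sga.item.muscle_atrophy:B",
                "sga.item.ankle_edema:B",
            ]
        )

    def test_exhaustive_oracle(self):
        """All 3^8 = 6561 rating vectors against a brute-force counter."""
        for combo in itertools.product("ABC", repeat=8):
            n_bc = sum(r != "A" for r in combo)
            n_c = sum(r == "C" for r in combo)
            result = diagnose_sga(list(combo))
            assert result.malnourished == (n_bc >= 5)
            if result.malnourished:
                assert result.severity == ("severe" if n_c >= 5 else "moderate")
            else:
                assert result.severity == "none"
            assert (result.severity == "severe") <= result.malnourished

    def test_invalid_rating_rejected(self):
        with pytest.raises(ValueError, match="gi_symptoms"):
            diagnose_sga(["A", "A", "D", "A", "A", "A", "A", "A"])

    def test_missing_items_policy(self):
        items = dict.fromkeys(SGA_ITEM_NAMES, "B")
        items["ankle_edema"] = None
        with pytest.raises(MissingDataError):
            diagnose_sga(items, policy="strict")
        assert diagnose_sga(items, policy="lenient").malnourished  # 7 B's count


class TestESPEN:
    def test_absolute_bmi_route(self):
        rec = make(age=72, nrs2002_total=3, bmi_kg_m2=18.0)
        result = diagnose_espen(rec)
        assert result.malnourished
        assert result.triggered_rules == ["espen.low_bmi_absolute"]

    def test_age_adjusted_route_young(self):
        rec = make(
            age=68, nrs2002_total=3, bmi_kg_m2=19.5, unintentional_weight_loss=True
        )
        result = diagnose_espen(rec)
        assert result.malnourished
        assert result.triggered_rules == ["espen.weight_loss_age_bmi"]

    def test_screening_gate_dominates(self):
        rec = make(age=72, nrs2002_total=2, bmi_kg_m2=17.0)
        assert not diagnose_espen(rec).malnourished

    def test_old_age_cutoff_22(self):
        rec = make(
            age=72, nrs2002_total=3, bmi_kg_m2=21.5, unintentional_weight_loss=True
        )
        assert diagnose_espen(rec).malnourished
        rec2 = make(
            age=69, nrs2002_total=3, bmi_kg_m2=21.5, unintentional_weight_loss=True
        )
        assert not diagnose_espen(rec2).malnourished


class TestGLIMRules:
    def test_muscle_mass_or_rule(self):
        rec = make(sex="male", calf_circumference_cm=33, grip_strength_kg=30)
        assert glim_phenotypic(rec) == {"glim.phenotypic.low_muscle_mass"}
        assert glim_phenotypic(rec, muscle_rule="and") == set()

    def test_low_bmi_age_dependence(self):
        assert glim_phenotypic(make(age=75, bmi_kg_m2=19.0)) == {
            "glim.phenotypic.low_bmi"
        }
        assert glim_phenotypic(make(age=66, bmi_kg_m2=19.0)) == set()

    def test_no_rule_fires(self):
        rec = make(
            age=66,
            sex="male",
            bmi_kg_m2=22,
            calf_circumference_cm=36,
            grip_strength_kg=35,
        )
        assert glim_phenotypic(rec) == set()

    def test_etiologic_albumin(self):
        assert glim_etiologic(make(albumin_g_L=33)) == {"glim.etiologic.inflammation"}
        assert glim_etiologic(make(albumin_g_L=40, intake_reduced_gt2wk=True)) == {
            "glim.etiologic.reduced_intake"
        }
        assert glim_etiologic(make(albumin_g_L=40)) == set()

    @pytest.mark.parametrize(
        "kw,severity",
        [
            (dict(weight_loss_pct_6mo=12.0), "severe"),
            (dict(age=75, bmi_kg_m2=16.8), "severe"),
            (dict(age=75, bmi_kg_m2=19.0, weight_loss_pct_6mo=6.0), "moderate"),
            (dict(weight_loss_pct_beyond_6mo=21.0), "severe"),
        ],
    )
    def test_severity(self, kw, severity):
        assert glim_severity(make(**kw)) == severity

    def test_full_diagnosis_composition(self):
        rec = make(age=75, nrs2002_total=3, bmi_kg_m2=19.0, albumin_g_L=33)
        result = diagnose_glim(rec)
        assert result.malnourished and result.severity == "moderate"
        assert result.triggered_rules == [
            "glim.etiologic.inflammation",
            "glim.phenotypic.low_bmi",
        ]

    def test_phenotypic_alone_insufficient(self):
        rec = make(age=75, nrs2002_total=3, bmi_kg_m2=19.0, albumin_g_L=40)
        assert not diagnose_glim(rec).malnourished

    def test_severe_weight_loss_path(self):
        rec = make(
            age=75, nrs2002_total=4, weight_loss_pct_6mo=12.0,
            intake_reduced_gt2wk=True, bmi_kg_m2=21.0,
        )
        result = diagnose_glim(rec)
        assert result.malnourished and result.severity == "severe"


class TestBoundaryStrictness:
    """Comparisons are strict exactly at the printed cutoffs."""

    def test_bmi_exactly_at_cutoff_does_not_fire(self):
        assert glim_phenotypic(make(age=66, bmi_kg_m2=18.5)) == set()
        assert glim_phenotypic(make(age=75, bmi_kg_m2=20.0)) == set()
        rec = make(age=66, nrs2002_total=3, bmi_kg_m2=18.5)
        assert not diagnose_espen(rec).malnourished

    def test_albumin_exactly_35_does_not_fire(self):
        assert glim_etiologic(make(albumin_g_L=35.0)) == set()

    def test_calf_grip_exact_cutoffs(self):
        rec = make(sex="male", calf_circumference_cm=34.0, grip_strength_kg=28.0)
        assert glim_phenotypic(rec) == set()
        rec = make(sex="female", calf_circumference_cm=33.0, grip_strength_kg=18.0)
        assert glim_phenotypic(rec) == set()

    def test_weight_loss_exactly_at_cutoff(self):
        assert glim_phenotypic(make(weight_loss_pct_6mo=5.0)) == set()
        assert glim_severity(make(weight_loss_pct_6mo=10.0, bmi_kg_m2=20)) == "moderate"


@st.composite
def record_strategy(draw):
    return make(
        age=draw(st.floats(min_value=65, max_value=100)),
        sex=draw(st.sampled_from(["male", "female"])),
        nrs2002_total=draw(st.integers(min_value=0, max_value=7)),
        bmi_kg_m2=draw(st.floats(min_value=12, max_value=40)),
        weight_loss_pct_6mo=draw(
            st.one_of(st.none(), st.floats(min_value=0, max_value=30))
        ),
        calf_circumference_cm=draw(
            st.one_of(st.none(), st.floats(min_value=20, max_value=45))
        ),
        grip_strength_kg=draw(
            st.one_of(st.none(), st.floats(min_value=0, max_value=60))
        ),
        albumin_g_L=draw(st.one_of(st.none(), st.floats(min_value=15, max_value=55))),
        unintentional_weight_loss=draw(st.booleans()),
        intake_reduced_gt2wk=draw(st.booleans()),
        inflammatory_condition=draw(st.booleans()),
    )


class TestProperties:
    @given(record_strategy())
    def test_gate_implication(self, rec):
        """Malnourished under GLIM or ESPEN implies NRS >= 3."""
        if diagnose_glim(rec).malnourished or diagnose_espen(rec).malnourished:
            assert rec.nrs2002_total >= 3

    @given(record_strategy())
    def test_severe_implies_malnourished(self, rec):
        result = diagnose_glim(rec)
        assert (result.severity in ("moderate", "severe")) == result.malnourished

    @given(record_strategy(), st.floats(min_value=0.5, max_value=6))
    def test_bmi_monotonicity(self, rec, delta):
        """Lowering BMI never flips any criterion to not-malnourished."""
        before_glim = diagnose_glim(rec).malnourished
        before_espen = diagnose_espen(rec).malnourished
        rec2 = rec.model_copy(update={"bmi_kg_m2": max(rec.bmi_kg_m2 - delta, 8.0)})
        assert diagnose_glim(rec2).malnourished >= before_glim
        assert diagnose_espen(rec2).malnourished >= before_espen

    @given(record_strategy(), st.floats(min_value=0.5, max_value=15))
    def test_albumin_monotonicity(self, rec, delta):
        """Raising albumin never adds an etiologic firing."""
        if rec.albumin_g_L is None:
            return
        before = glim_etiologic(rec)
        rec2 = rec.model_copy(update={"albumin_g_L": rec.albumin_g_L + delta})
        assert glim_etiologic(rec2) <= before


class TestCohortDiagnosis:
    def test_vectorized_agrees_with_scalar(self):
        """diagnose_all equals the per-record reference engines row by row."""
        rng = np.random.default_rng(7)
        df = random_record_frame(rng, 400)
        dx = diagnose_all(df)
        from malnutdx.io import frame_to_records

        for i, rec in enumerate(frame_to_records(df)):
            g = diagnose_glim(rec)
            e = diagnose_espen(rec)
            s = diagnose_sga(rec.sga_items, policy="lenient")
            assert bool(dx["glim_status"].iat[i]) == g.malnourished, i
            assert dx["glim_severity"].iat[i] == g.severity, i
            assert bool(dx["espen_status"].iat[i]) == e.malnourished, i
            assert bool(dx["sga_status"].iat[i]) == s.malnourished, i
            assert dx["sga_severity"].iat[i] == s.severity, i

    def test_strict_policy_raises_on_missing(self):
        rng = np.random.default_rng(1)
        df = random_record_frame(rng, 50)
        df.loc[0, "bmi_kg_m2"] = np.nan
        with pytest.raises(MissingDataError):
            diagnose_all(df, policy="strict")

    def test_prevalence_summary_counts(self, default_cohort):
        cohort, _ = default_cohort
        dx = diagnose_all(cohort)
        summary = prevalence_summary(dx)
        glim = summary.query("criterion == 'GLIM' and stratum == 'malnourished'")
        assert glim["count"].iat[0] == dx["glim_status"].sum()
        mod = summary.query("criterion == 'GLIM' and stratum == 'moderate'")["count"].iat[0]
        sev = summary.query("criterion == 'GLIM' and stratum == 'severe'")["count"].iat[0]
        assert mod + sev == glim["count"].iat[0]

    def test_empty_cohort(self):
        import pandas as pd

        dx = diagnose_all(pd.DataFrame(columns=["patient_id", "age", "sex"]))
        assert len(dx) == 0
        summary = prevalence_summary(dx)
        assert summary["count"].eq(0).all()
        assert summary["percent"].isna().all()

    def test_threshold_override_monotone(self):
        """Lowering the albumin cutoff can only reduce inflammation firings."""
        rng = np.random.default_rng(11)
        df = random_record_frame(rng, 500)
        base = diagnose_all(df)
        tighter = diagnose_all(df, CriteriaThresholds(albumin_inflammation=30.0))
        assert (
            tighter["glim_rule_inflammation"].sum()
            <= base["glim_rule_inflammation"].sum()
        )
        assert not (tighter["glim_status"] & ~base["glim_status"]).any()
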