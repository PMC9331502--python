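"""Group comparisons, covariate screening, logistic models, RF importance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from malnutdx.diagnostics import diagnose_all
from malnutdx.outcomes import (
    DegenerateDataError,
    RFConfig,
    SeparationError,
    descriptive_outcomes,
    fit_logistic,
    group_compare,
    rf_importance,
    spearman_screen,
)
from malnutdx.synthetic import CohortConfig, generate_cohort


class TestGroupCompare:
    def test_categorical_percentages(self):
        # 60/956 vs 43/1570 complication pattern
        g = np.repeat([True, False], [956, 1570])
        y = np.zeros(2526, dtype=bool)
        y[:60] = True
        y[956 : 956 + 43] = True
        df = pd.DataFrame({"complication": y})
        comp = group_compare(df, g, "complication")
        assert comp.group_summaries["malnourished"] == "60(6.3)"
        assert comp.group_summaries["normal"] == "43(2.7)"
        assert comp.test == "chi_square"
        assert comp.p_value < 0.001

    def test_chi_square_matches_hand_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c, d = rng.integers(5, 200, 4)
            g = np.repeat([True, True, False, False], [a, b, c, d])
            y = np.repeat([True, False, True, False], [a, b, c, d])
            comp = group_compare(pd.DataFrame({"y": y}), g, "y")
            n = a + b + c + d
            hand = (
                n
                * (a * d - b * c) ** 2
                / ((a + b) * (c + d) * (a + c) * (b + d))
            )
            if comp.test == "chi_square":
                assert comp.statistic == pytest.approx(hand, rel=1e-10)

    def test_fisher_when_expected_below_5(self):
        g = np.repeat([True, False], [10, 200])
        y = np.zeros(210, dtype=bool)
        y[:2] = True
        comp = group_compare(pd.DataFrame({"y": y}), g, "y")
        assert comp.test == "fisher_exact"

    def test_identical_balanced_groups_p_one(self):
        g = np.repeat([True, False], 100)
        y = np.tile(np.repeat([True, False], 50), 2)
        comp = group_compare(pd.DataFrame({"y": y}), g, "y")
        assert comp.p_value == pytest.approx(1.0)

    def test_normal_continuous_uses_t(self):
        rng = np.random.default_rng(2)
        g = np.repeat([True, False], 150)
        x = np.concatenate([rng.normal(10, 2, 150), rng.normal(11, 2, 150)])
        comp = group_compare(pd.DataFrame({"x": x}), g, "x")
        assert comp.test == "t_test" and comp.normal is True
        assert "±" in comp.group_summaries["malnourished"]

    def test_skewed_continuous_uses_mann_whitney(self):
        rng = np.random.default_rng(3)
        g = np.repeat([True, False], 1263)
        x = rng.lognormal(2.6, 0.4, 2526)
        comp = group_compare(pd.DataFrame({"x": x}), g, "x")
        assert comp.test == "mann_whitney" and comp.normal is False
        assert "(" in comp.group_summaries["normal"]  # median(QD) format

    def test_constant_values_fall_back(self):
        g = np.repeat([True, False], 10)
        comp = group_compare(pd.DataFrame({"x": np.zeros(20)}), g, "x")
        assert comp.test == "none" and np.isnan(comp.p_value)

    def test_empty_group_raises(self):
        with pytest.raises(DegenerateDataError):
            group_compare(pd.DataFrame({"x": [1.0, 2.0]}), np.array([True, True]), "x")


class TestSpearman:
    def test_monotone_transform_rho_one(self):
        x = np.linspace(0, 10, 50)
        df = pd.DataFrame({"x": x, "y": np.exp(x), "z": -x})
        out = spearman_screen(df, ["x", "y", "z"]).set_index(["var1", "var2"])
        assert out.loc[("x", "y"), "rho"] == pytest.approx(1.0)
        assert out.loc[("x", "z"), "rho"] == pytest.approx(-1.0)
        assert out.loc[("x", "y"), "collinear"]

    def test_independent_uniforms_small_rho(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.random(1000), "b": rng.random(1000)})
        out = spearman_screen(df, ["a", "b"])
        assert abs(out["rho"].iat[0]) < 0.1

    def test_constant_variable_flagged(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        out = spearman_screen(df, ["a", "b"])
        assert np.isnan(out["rho"].iat[0]) and out["collinear"].iat[0]


class TestLogistic:
    def test_null_model_or_near_one(self):
        rng = np.random.default_rng(4)
        n = 4000
        df = pd.DataFrame(
            {
                "glim_status": rng.random(n) < 0.4,
                "age": rng.uniform(65, 90, n),
                "sex": rng.choice(["male", "female"], n),
                "marital_status": rng.choice(["married", "other"], n),
                "total_complication": rng.random(n) < 0.1,
            }
        )
        model = fit_logistic(df, "glim_status")
        assert model.odds_ratio() == pytest.approx(1.0, abs=0.35)
        assert model.model_id == "Model1_GLIM"
        row = model.coef_table.set_index("term").loc["malnutrition"]
        assert row["ci_lo"] < 1.0 < row["ci_hi"]
        assert np.exp(row["estimate"]) == pytest.approx(row["or_"])

    def test_separation_raises(self):
        # outcome identical to the malnutrition indicator: MLE diverges
        rng = np.random.default_rng(6)
        g = np.array([True] * 30 + [False] * 30)
        df = pd.DataFrame(
            {
                "glim_status": g,
                "age": rng.uniform(65, 90, 60),
                "sex": rng.choice(["male", "female"], 60),
                "marital_status": rng.choice(["married", "other"], 60),
                "total_complication": g,
            }
        )
        with pytest.raises(SeparationError):
            fit_logistic(df, "glim_status")

    def test_degenerate_outcome_raises(self):
        df = pd.DataFrame(
            {
                "glim_status": [True, False] * 10,
                "age": np.linspace(65, 80, 20),
                "sex": ["male", "female"] * 10,
                "marital_status": ["married"] * 20,
                "total_complication": [False] * 20,
            }
        )
        with pytest.raises(DegenerateDataError):
            fit_logistic(df, "glim_status")

    def test_recovers_planted_or_on_synthetic_cohorts(self):
        """Median estimated OR near truth over a batch of seeded cohorts."""
        ors = []
        for seed in range(40):
            cohort, _ = generate_cohort(CohortConfig(seed=5000 + seed))
            dx = diagnose_all(cohort)
            df = cohort.assign(glim_status=dx["glim_status"])
            ors.append(fit_logistic(df, "glim_status").odds_ratio())
        assert np.median(ors) == pytest.approx(2.414, abs=0.3)


class TestRFImportance:
    @pytest.fixture(scope="class")
    def feature_table(self):
        rng = np.random.default_rng(9)
        n = 1200
        x = rng.random(n) < 0.4
        eta = -2.2 + 1.6 * x
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        return (
            pd.DataFrame(
                {
                    "signal": x.astype(int),
                    "age": rng.uniform(65, 90, n),
                    "noise": rng.random(n),
                }
            ),
            pd.Series(y),
        )

    def test_deterministic(self, feature_table):
        X, y = feature_table
        cfg = RFConfig(seed=11, n_splits=2, n_trees=100)
        a = rf_importance(X, y, cfg)
        b = rf_importance(X, y, cfg)
        pd.testing.assert_frame_equal(a.importances, b.importances)

    def test_signal_beats_noise(self, feature_table):
        X, y = feature_table
        rep = rf_importance(X, y, RFConfig(seed=1, n_splits=3, n_trees=200))
        imp = rep.importances.set_index("feature")
        assert (
            imp.loc["signal", "mean_decrease_accuracy"]
            > imp.loc["noise", "mean_decrease_accuracy"]
        )
        assert abs(imp.loc["noise", "mean_decrease_accuracy"]) < 0.02
        assert rep.ranking()[0] == "signal"

    def test_degenerate_outcome(self, feature_table):
        X, _ = feature_table
        with pytest.raises(DegenerateDataError):
            rf_importance(X, pd.Series(np.zeros(len(X), dtype=int)))


class TestDescriptiveOutcomes:
    def test_table_structure_and_sparse_flags(self, default_cohort):
        cohort, _ = default_cohort
        dx = diagnose_all(cohort)
        table = descriptive_outcomes(cohort, dx)
        assert set(table["criterion"]) == {"glim_status", "sga_status", "espen_status"}
        # sparse binary outcomes (< 10 events cohort-wide) have the test
        # suppressed; well-populated ones keep it
        for outcome in ("mortality", "total_complication", "icu_admission"):
            events = int(cohort[outcome].sum())
            rows = table.query("outcome == @outcome")
            assert rows["descriptive_only"].eq(events < 10).all(), outcome
        sparse = table.query("descriptive_only")
        assert sparse.empty or (
            sparse["test"].eq("suppressed").all() and sparse["p_value"].isna().all()
        )
        los = table.query("criterion == 'glim_status' and outcome == 'los_days'")
        assert los["test"].iat[0] in ("mann_whitney", "t_test")

    def test_malnourished_los_longer_under_all_criteria(self, default_cohort):
        cohort, _ = default_cohort
        dx = diagnose_all(cohort)
        for crit in ("glim_status", "sga_status", "espen_status"):
            g = dx[crit].to_numpy()
            assert (
                cohort["los_days"][g].mean() > cohort["los_days"][~g].mean()
            ), crit

    def test_overall_complication_incidence_near_target(self, default_cohort):
        cohort, _ = default_cohort
        inc = cohort["total_complication"].mean()
        # baseline 2.7% in GLIM-normal, OR 2.414 in the 38% malnourished
        # stratum gives ~4% overall
        assert 0.03 < inc < 0.055
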