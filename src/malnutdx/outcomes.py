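"""Outcome-association analyses for malnourished vs normal inpatients.

Covers the downstream statistics of the pipeline:

* :func:`group_compare` — two-group comparisons with a Shapiro-Wilk
  normality gate (alpha = 0.05): chi-square (no continuity correction,
  Fisher exact when any expected cell < 5) for categorical outcomes,
  Student's t for normal continuous outcomes, Mann-Whitney U otherwise.
  Continuous summaries follow the gate: mean +/- SD when normal, median
  and quartile deviation (QD = (Q3 - Q1)/2) when not.
* :func:`spearman_screen` — pairwise Spearman rank correlations on
  complete cases, flagging collinear covariate pairs.
* :func:`fit_logistic` — multivariable logistic regression of a binary
  outcome on a malnutrition indicator adjusted for age, gender and marital
  status (male = 1, married = 1, age in years), reporting per-term odds
  ratios with Wald 95% CIs.
* :func:`rf_importance` — random-forest permutation importance. "Mean
  decrease in accuracy" is computed per tree on a 25% held-out partition
  (accuracy drop after permuting one feature, averaged over trees and over
  split replicates); "mean decrease in Gini" is the per-tree unnormalized
  impurity-decrease attribution averaged over the forest.
* :func:`descriptive_outcomes` — a full malnourished-vs-normal outcome
  table per criterion, with sparse outcomes (< ``min_events`` events)
  reported descriptively without a test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
)

SHAPIRO_ALPHA = 0.05
_SHAPIRO_MAX_N = 4999  # scipy's implementation degrades above ~5000


class DegenerateDataError(Exception):
    """A statistic's preconditions fail (empty group, constant outcome...)."""


class SeparationError(Exception):
    """Perfect separation: the logistic MLE does not exist."""


# ---------------------------------------------------------------------------
# Group comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    outcome: str
    kind: str  # "categorical" | "continuous"
    test: str  # "chi_square" | "fisher_exact" | "t_test" | "mann_whitney" | "none"
    p_value: float
    group_summaries: dict[str, str]
    statistic: float = float("nan")
    normal: Optional[bool] = None  # Shapiro gate outcome (continuous only)


def _is_categorical(values: pd.Series) -> bool:
    if values.dtype == bool or isinstance(values.dtype, pd.CategoricalDtype):
        return True
    if values.dtype == object or pd.api.types.is_string_dtype(values):
        return True
    return False


def _shapiro_normal(x: np.ndarray) -> bool:
    """Normality gate; all-identical values are treated as non-normal."""
    if np.ptp(x) == 0:
        return False
    if len(x) > _SHAPIRO_MAX_N:
        x = np.random.default_rng(0).choice(x, _SHAPIRO_MAX_N, replace=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return stats.shapiro(x).pvalue >= SHAPIRO_ALPHA


def group_compare(
    cohort: pd.DataFrame,
    grouping: Union[str, pd.Series, np.ndarray],
    outcome: str,
    group_names: tuple[str, str] = ("malnourished", "normal"),
) -> GroupComparison:
    """Compare one outcome between a binary grouping's two strata.

    ``grouping`` is a column name or boolean vector (True = first group).
    Test selection is a pure function of the outcome's type and, for
    continuous outcomes, the Shapiro-Wilk gate applied per group.
    """
    g = cohort[grouping] if isinstance(grouping, str) else pd.Series(grouping)
    g = g.astype(bool).to_numpy()
    values = cohort[outcome]
    mask = values.notna().to_numpy()
    g, values = g[mask], values[mask]
    n1, n0 = int(g.sum()), int((~g).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateDataError(f"empty group for outcome {outcome!r}")

    if _is_categorical(values):
        tab = pd.crosstab(g, values)
        pos = values.astype(bool) if values.dtype == bool else None
        summaries = {}
        for name, sel in zip(group_names, (g, ~g)):
            if pos is not None:
                k = int(pos[sel].sum())
                summaries[name] = f"{k}({100 * k / sel.sum():.1f})"
            else:
                counts = values[sel].value_counts()
                summaries[name] = ", ".join(
                    f"{lvl}:{cnt}({100 * cnt / sel.sum():.1f})"
                    for lvl, cnt in counts.items()
                )
        if tab.shape[1] < 2:
            # outcome constant: no test possible
            return GroupComparison(outcome, "categorical", "none", float("nan"), summaries)
        expected = stats.contingency.expected_freq(tab.to_numpy())
        if tab.shape == (2, 2) and (expected < 5).any():
            stat, p = stats.fisher_exact(tab.to_numpy())
            test = "fisher_exact"
        else:
            stat, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
            test = "chi_square"
        return GroupComparison(outcome, "categorical", test, float(p), summaries, float(stat))

    x1 = values[g].to_numpy(dtype=float)
    x0 = values[~g].to_numpy(dtype=float)
    if len(x1) < 2 or len(x0) < 2:
        raise DegenerateDataError(f"need >= 2 values per group for {outcome!r}")
    normal = _shapiro_normal(x1) and _shapiro_normal(x0)
    if normal:
        stat, p = stats.ttest_ind(x1, x0, equal_var=True)
        test = "t_test"
        summaries = {
            name: f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
            for name, x in zip(group_names, (x1, x0))
        }
    else:
        if np.ptp(np.concatenate([x1, x0])) == 0:
            return GroupComparison(
                outcome,
                "continuous",
                "none",
                float("nan"),
                {name: f"{np.median(x):.2f}(0.00)" for name, x in zip(group_names, (x1, x0))},
                normal=False,
            )
        stat, p = stats.mannwhitneyu(x1, x0, alternative="two-sided")
        test = "mann_whitney"
        summaries = {}
        for name, x in zip(group_names, (x1, x0)):
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            summaries[name] = f"{med:.2f}({(q3 - q1) / 2:.2f})"
    return GroupComparison(
        outcome, "continuous", test, float(p), summaries, float(stat), bool(normal)
    )


# ---------------------------------------------------------------------------
# Covariate screening
# ---------------------------------------------------------------------------

def spearman_screen(
    cohort: pd.DataFrame,
    variables: Sequence[str],
    collinearity_threshold: float = 0.8,
) -> pd.DataFrame:
    """Pairwise Spearman rho with p-values on complete cases.

    Returns a long-format frame (var1, var2, rho, p_value, n, collinear);
    a constant variable yields NaN rho and is flagged.
    """
    rows = []
    for i, v1 in enumerate(variables):
        for v2 in variables[i + 1:]:
            pair = cohort[[v1, v2]].dropna()
            x = pd.to_numeric(pair[v1], errors="coerce")
            y = pd.to_numeric(pair[v2], errors="coerce")
            ok = x.notna() & y.notna()
            x, y = x[ok], y[ok]
            if len(x) < 3:
                raise DegenerateDataError(
                    f"fewer than 3 complete pairs for ({v1}, {v2})"
                )
            if x.nunique() < 2 or y.nunique() < 2:
                rho, p = float("nan"), float("nan")
                collinear = True  # constant variable: flagged, not usable
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rho, p = stats.spearmanr(x, y)
                collinear = abs(rho) >= collinearity_threshold
            rows.append(
                {
                    "var1": v1,
                    "var2": v2,
                    "rho": float(rho),
                    "p_value": float(p),
                    "n": int(len(x)),
                    "collinear": bool(collinear),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Logistic association models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AssociationModel:
    """One fitted malnutrition-adjusted logistic model."""

    model_id: str
    coef_table: pd.DataFrame  # term, estimate, or_, ci_lo, ci_hi, p_value
    n_used: int
    converged: bool
    reference_coding: dict[str, str] = field(default_factory=dict)

    def odds_ratio(self, term: str = "malnutrition") -> float:
        row = self.coef_table.set_index("term").loc[term]
        return float(row["or_"])

    def summary(self) -> str:
        lines = [f"Logistic model {self.model_id} (n={self.n_used})"]
        for _, row in self.coef_table.iterrows():
            lines.append(
                f"  {row['term']:<16} OR {row['or_']:.3f} "
                f"({row['ci_lo']:.3f}-{row['ci_hi']:.3f})  p={row['p_value']:.4g}"
            )
        return "\n".join(lines)


_MODEL_IDS = {
    "glim_status": "Model1_GLIM",
    "sga_status": "Model2_SGA",
    "espen_status": "Model3_ESPEN",
}


def fit_logistic(
    cohort: pd.DataFrame,
    dx_column: str,
    covariates: Sequence[str] = ("age", "sex", "marital_status"),
    outcome: str = "total_complication",
    complete_cases: bool = True,
) -> AssociationModel:
    """Adjusted odds ratio of a malnutrition indicator for a binary outcome.

    Coding: malnutrition 1 = malnourished; sex 1 = male; marital_status
    1 = married; age continuous in years. Maximum-likelihood fit; perfect
    separation raises :class:`SeparationError`, a degenerate outcome raises
    :class:`DegenerateDataError`.
    """
    cols = [outcome, dx_column, *covariates]
    data = cohort[cols].dropna() if complete_cases else cohort[cols]
    y = data[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise DegenerateDataError(f"outcome {outcome!r} is degenerate")

    design = pd.DataFrame(index=data.index)
    coding: dict[str, str] = {dx_column: "1 = malnourished"}
    design["malnutrition"] = data[dx_column].astype(bool).astype(float)
    for cov in covariates:
        col = data[cov]
        if cov == "sex":
            design["gender"] = (col.astype(str) == "male").astype(float)
            coding["sex"] = "1 = male (reference: female)"
        elif cov == "marital_status":
            design["married"] = (col.astype(str) == "married").astype(float)
            coding["marital_status"] = "1 = married (reference: other)"
        elif _is_categorical(col):
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            design = pd.concat([design, dummies.astype(float)], axis=1)
            coding[cov] = f"dummy-coded, reference = {sorted(col.astype(str).unique())[0]}"
        else:
            design[cov] = col.astype(float)
            coding[cov] = "continuous"

    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise DegenerateDataError("design matrix is rank deficient")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.filterwarnings("ignore", message="divide by zero")
            # non-convergence is detected from mle_retvals and raised as a
            # typed error below; the warning itself is redundant
            warnings.filterwarnings("ignore", category=ConvergenceWarning)
            result = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except PerfectSeparationError as exc:
        raise SeparationError(str(exc)) from exc
    except RuntimeWarning as exc:  # statsmodels downgraded separation to a warning
        raise SeparationError(str(exc)) from exc
    except np.linalg.LinAlgError as exc:
        # singular Hessian at the boundary: separation in disguise
        raise SeparationError(f"singular Hessian: {exc}") from exc
    if not result.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    if np.abs(result.params).max() > 15:
        raise SeparationError("implausibly large coefficients: likely separation")

    terms = ["intercept", *design.columns]
    conf = result.conf_int()
    coef_table = pd.DataFrame(
        {
            "term": terms,
            "estimate": result.params,
            "or_": np.exp(result.params),
            "ci_lo": np.exp(conf[:, 0]),
            "ci_hi": np.exp(conf[:, 1]),
            "p_value": result.pvalues,
        }
    )
    return AssociationModel(
        model_id=_MODEL_IDS.get(dx_column, dx_column),
        coef_table=coef_table,
        n_used=int(len(y)),
        converged=bool(result.mle_retvals.get("converged", False)),
        reference_coding=coding,
    )


# ---------------------------------------------------------------------------
# Random-forest importance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RFConfig:
    split: float = 0.75  # training fraction
    n_trees: int = 500
    n_splits: int = 10  # split replicates importances are averaged over
    seed: int = 0


@dataclass(frozen=True)
class ImportanceReport:
    importances: pd.DataFrame  # feature, mean_decrease_accuracy, mean_decrease_gini
    config: RFConfig
    n_rows: int

    def ranking(self, measure: str = "mean_decrease_accuracy") -> list[str]:
        return (
            self.importances.sort_values(measure, ascending=False)["feature"].tolist()
        )


def rf_importance(
    feature_table: pd.DataFrame,
    outcome: Union[str, pd.Series, np.ndarray],
    config: RFConfig = RFConfig(),
) -> ImportanceReport:
    """Permutation and Gini importance of features for a binary outcome.

    Deterministic in (data, config): all randomness (splits, forests,
    permutations) derives from ``config.seed``.
    """
    if isinstance(outcome, str):
        y = feature_table[outcome].astype(int).to_numpy()
        X_df = feature_table.drop(columns=[outcome])
    else:
        y = pd.Series(outcome).astype(int).to_numpy()
        X_df = feature_table
    X = X_df.astype(float).to_numpy()
    features = list(X_df.columns)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("outcome is degenerate (single class)")
    n_test = int(round(len(y) * (1 - config.split)))
    if n_test < 2 or len(y) - n_test < 2:
        raise DegenerateDataError("too few rows for the requested split")

    ss = np.random.SeedSequence(config.seed)
    split_seeds = ss.generate_state(2 * config.n_splits).reshape(config.n_splits, 2)
    mda = np.zeros((config.n_splits, len(features)))
    mdg = np.zeros((config.n_splits, len(features)))
    for r, (split_seed, rf_seed) in enumerate(split_seeds):
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            train_size=config.split,
            random_state=int(split_seed % (2**31)),
            stratify=y,
        )
        forest = RandomForestClassifier(
            n_estimators=config.n_trees, random_state=int(rf_seed % (2**31)), n_jobs=1
        )
        forest.fit(X_tr, y_tr)
        rng = np.random.default_rng(int(rf_seed))
        base_preds = np.stack([t.predict(X_te) for t in forest.estimators_])
        base_acc = (base_preds == y_te).mean(axis=1)  # per-tree accuracy
        for j in range(len(features)):
            X_perm = X_te.copy()
            X_perm[:, j] = rng.permutation(X_perm[:, j])
            preds = np.stack([t.predict(X_perm) for t in forest.estimators_])
            acc = (preds == y_te).mean(axis=1)
            mda[r, j] = (base_acc - acc).mean()
        mdg[r] = np.mean(
            [
                t.tree_.compute_feature_importances(normalize=False)
                for t in forest.estimators_
            ],
            axis=0,
        )
    importances = pd.DataFrame(
        {
            "feature": features,
            "mean_decrease_accuracy": mda.mean(axis=0),
            "mean_decrease_gini": mdg.mean(axis=0),
        }
    )
    return ImportanceReport(importances=importances, config=config, n_rows=len(y))


# ---------------------------------------------------------------------------
# Descriptive outcome table
# ---------------------------------------------------------------------------

OUTCOME_ROWS = (
    ("total_complication", "categorical"),
    ("infectious_complication", "categorical"),
    ("noninfectious_complication", "categorical"),
    ("icu_admission", "categorical"),
    ("mortality", "categorical"),
    ("los_days", "continuous"),
    ("icu_days", "continuous"),
    ("expenses_usd", "continuous"),
)


def descriptive_outcomes(
    cohort: pd.DataFrame,
    dx_table: pd.DataFrame,
    criteria: Sequence[str] = ("glim_status", "sga_status", "espen_status"),
    min_events: int = 10,
) -> pd.DataFrame:
    """Malnourished-vs-normal outcome comparison per diagnostic criterion.

    Binary outcomes with fewer than ``min_events`` events across the cohort
    are rendered descriptively (test suppressed, ``descriptive_only``).
    """
    rows = []
    for crit in criteria:
        g = dx_table[crit].astype(bool).to_numpy()
        for outcome, kind in OUTCOME_ROWS:
            if outcome not in cohort.columns:
                continue
            values = cohort[outcome]
            sparse = False
            if kind == "categorical":
                events = int(values.fillna(False).astype(bool).sum())
                sparse = events < min_events
            try:
                comp = group_compare(cohort, g, outcome)
            except DegenerateDataError:
                continue
            rows.append(
                {
                    "criterion": crit,
                    "outcome": outcome,
                    "malnourished": comp.group_summaries["malnourished"],
                    "normal": comp.group_summaries["normal"],
                    "test": "suppressed" if sparse else comp.test,
                    "p_value": float("nan") if sparse else comp.p_value,
                    "descriptive_only": sparse,
                }
            )
    return pd.DataFrame(rows)
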