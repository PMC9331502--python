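"""Agreement statistics between two binary malnutrition diagnoses.

Everything is computed from a 2x2 cross-classification of a *test*
criterion against a *reference* criterion (conventionally the bedside SGA
as the semi-gold standard):

====  =====  =====
      ref+   ref-
====  =====  =====
test+  a      b
test-  c      d
====  =====  =====

* sensitivity = a/(a+c), specificity = d/(b+d), accuracy = (a+d)/n, each
  with a 95% Wilson score interval (score-test inversion, no continuity
  correction — the interval is exact at the 0/1 boundaries, e.g. the lower
  bound for x = n successes is n/(n + z^2)).
* Cohen's kappa = (p_o - p_e)/(1 - p_e) with p_o the observed and p_e the
  chance agreement from the marginal products, with a delta-method
  (Fleiss-Cohen-Everitt) standard error or an optional nonparametric
  bootstrap.
* Interpretation bands: [0, 0.20) weak, [0.20, 0.4) low, [0.4, 0.6)
  medium, [0.6, 0.8) good, [0.8, 1] excellent.

Undefined statistics (zero denominators, degenerate marginals) are
signalled as NaN, never silently reported as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionTable2x2",
    "ConcordanceStats",
    "build_confusion",
    "proportion_stats",
    "wilson_ci",
    "cohens_kappa",
    "kappa_ci",
    "interpret_kappa",
    "concordance_report",
]


@dataclass(frozen=True)
class ConfusionTable2x2:
    """Cross-classification counts of two binary raters."""

    a: int  # test+, ref+
    b: int  # test+, ref-
    c: int  # test-, ref+
    d: int  # test-, ref-
    label: str = ""

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.n == 0:
            raise ValueError("empty 2x2 table: no statistic is defined")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def transpose(self) -> "ConfusionTable2x2":
        """Swap the test/reference roles (b and c exchange)."""
        return ConfusionTable2x2(self.a, self.c, self.b, self.d, self.label)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def build_confusion(
    test_labels: Sequence, ref_labels: Sequence, label: str = ""
) -> ConfusionTable2x2:
    """Cross-classify two equal-length binary label vectors."""
    test = np.asarray(test_labels)
    ref = np.asarray(ref_labels)
    if test.shape != ref.shape or test.ndim != 1:
        raise ValueError("test and reference label vectors must be equal-length 1-D")
    if len(test) == 0:
        raise ValueError("empty label vectors")
    for vec, name in ((test, "test"), (ref, "ref")):
        uniq = set(np.unique(vec).tolist())
        if not uniq <= {0, 1, True, False}:
            raise ValueError(f"{name} labels must be binary (0/1), got {sorted(uniq)}")
    test = test.astype(bool)
    ref = ref.astype(bool)
    return ConfusionTable2x2(
        a=int((test & ref).sum()),
        b=int((test & ~ref).sum()),
        c=int((~test & ref).sum()),
        d=int((~test & ~ref).sum()),
        label=label,
    )


def proportion_stats(t: ConfusionTable2x2) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy); NaN where the denominator is 0."""
    sens = t.a / (t.a + t.c) if (t.a + t.c) > 0 else float("nan")
    spec = t.d / (t.b + t.d) if (t.b + t.d) > 0 else float("nan")
    acc = (t.a + t.d) / t.n
    return sens, spec, acc


def wilson_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, no continuity correction."""
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts: {successes}/{trials}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf((1 + level) / 2)
    p = successes / trials
    denom = 1 + z**2 / trials
    centre = (p + z**2 / (2 * trials)) / denom
    half = (z / denom) * np.sqrt(p * (1 - p) / trials + z**2 / (4 * trials**2))
    lo, hi = centre - half, centre + half
    if successes == 0:
        lo = 0.0  # exact at the boundary; avoids 1e-18 float residue
    if successes == trials:
        hi = 1.0
    return max(0.0, float(lo)), min(1.0, float(hi))


def cohens_kappa(t: ConfusionTable2x2) -> float:
    """Chance-corrected agreement between the two raters.

    p_e is the expected agreement from the marginal products. In the fully
    degenerate case p_e = 1 (all mass in one cell) observed agreement is
    also perfect and kappa is reported as 1.0 by convention.
    """
    n = t.n
    po = (t.a + t.d) / n
    pe = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / n**2
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def kappa_se(t: ConfusionTable2x2) -> float:
    """Large-sample delta-method standard error of Cohen's kappa.

    The Fleiss-Cohen-Everitt variance for a k x k agreement table,
    specialised here to 2 x 2. NaN when the marginals are degenerate.
    """
    n = t.n
    p = t.as_array() / n
    pi_row = p.sum(axis=1)  # test marginals
    pi_col = p.sum(axis=0)  # reference marginals
    po = p[0, 0] + p[1, 1]
    pe = float(pi_row @ pi_col)
    if pe == 1.0:
        return float("nan")
    term1 = sum(
        p[i, i] * ((1 - pe) - (pi_row[i] + pi_col[i]) * (1 - po)) ** 2
        for i in range(2)
    )
    term2 = (1 - po) ** 2 * sum(
        p[i, j] * (pi_col[i] + pi_row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    term3 = (po * pe - 2 * pe + po) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 4)
    return float(np.sqrt(max(var, 0.0)))


def kappa_ci(
    t: ConfusionTable2x2,
    level: float = 0.95,
    method: str = "delta",
    n_boot: int = 2000,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """95% (by default) CI for kappa, clamped to [-1, 1].

    ``method="delta"`` uses the analytic standard error;
    ``method="bootstrap"`` resamples the n paired labels with replacement.
    Degenerate marginals yield (NaN, NaN).
    """
    k = cohens_kappa(t)
    if method == "delta":
        se = kappa_se(t)
        if np.isnan(se):
            return float("nan"), float("nan")
        z = stats.norm.ppf((1 + level) / 2)
        return max(-1.0, k - z * se), min(1.0, k + z * se)
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        cells = np.array([t.a, t.b, t.c, t.d])
        draws = rng.multinomial(t.n, cells / t.n, size=n_boot)
        ks = []
        for a, b, c, d in draws:
            tab = np.array([[a, b], [c, d]], dtype=float)
            po = (a + d) / t.n
            pe = ((a + b) * (a + c) + (c + d) * (b + d)) / t.n**2
            ks.append(1.0 if pe == 1.0 else (po - pe) / (1 - pe))
        alpha = 1 - level
        lo, hi = np.quantile(ks, [alpha / 2, 1 - alpha / 2])
        return float(max(-1.0, lo)), float(min(1.0, hi))
    raise ValueError(f"unknown CI method {method!r}")


_BANDS = (
    (0.20, "weak"),
    (0.40, "low"),
    (0.60, "medium"),
    (0.80, "good"),
    (1.0 + 1e-12, "excellent"),
)


def interpret_kappa(kappa: float) -> str:
    """Consistency band for a kappa value; negative values read as weak
    (below-chance agreement)."""
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa must lie in [-1, 1], got {kappa}")
    if kappa < 0:
        return "weak"
    for upper, band in _BANDS:
        if kappa < upper:
            return band
    return "excellent"


def _round_half_up(x: float, digits: int) -> float:
    return float(Decimal(str(float(x))).quantize(Decimal(f"1e-{digits}"), ROUND_HALF_UP))


@dataclass(frozen=True)
class ConcordanceStats:
    """Agreement report of a test criterion against a reference criterion."""

    table: ConfusionTable2x2
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    kappa: float
    kappa_ci: tuple[float, float]
    kappa_band: str

    def summary(self) -> str:
        """Human-readable report: percentages at 2 dp, kappa at 3 dp."""

        def pct(x: float) -> str:
            return "undefined" if np.isnan(x) else f"{_round_half_up(100 * x, 2):.2f}%"

        def pct_ci(ci: tuple[float, float]) -> str:
            if any(np.isnan(v) for v in ci):
                return "(undefined)"
            return f"({pct(ci[0])}, {pct(ci[1])})"

        lines = [
            f"Concordance {self.table.label or 'test vs reference'}"
            f"  (n={self.table.n}; a={self.table.a}, b={self.table.b},"
            f" c={self.table.c}, d={self.table.d})",
            f"  accuracy    {pct(self.accuracy)} {pct_ci(self.accuracy_ci)}",
            f"  sensitivity {pct(self.sensitivity)} {pct_ci(self.sensitivity_ci)}",
            f"  specificity {pct(self.specificity)} {pct_ci(self.specificity_ci)}",
            f"  kappa       {_round_half_up(self.kappa, 3):.3f}"
            f" ({_round_half_up(self.kappa_ci[0], 3):.3f},"
            f" {_round_half_up(self.kappa_ci[1], 3):.3f})  [{self.kappa_band}]",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "label": self.table.label,
                    "n": self.table.n,
                    "a": self.table.a,
                    "b": self.table.b,
                    "c": self.table.c,
                    "d": self.table.d,
                    "sensitivity": self.sensitivity,
                    "sensitivity_lo": self.sensitivity_ci[0],
                    "sensitivity_hi": self.sensitivity_ci[1],
                    "specificity": self.specificity,
                    "specificity_lo": self.specificity_ci[0],
                    "specificity_hi": self.specificity_ci[1],
                    "accuracy": self.accuracy,
                    "accuracy_lo": self.accuracy_ci[0],
                    "accuracy_hi": self.accuracy_ci[1],
                    "kappa": self.kappa,
                    "kappa_lo": self.kappa_ci[0],
                    "kappa_hi": self.kappa_ci[1],
                    "kappa_band": self.kappa_band,
                }
            ]
        )


def stats_from_table(
    t: ConfusionTable2x2, level: float = 0.95, kappa_method: str = "delta"
) -> ConcordanceStats:
    """All agreement statistics from one 2x2 table."""
    sens, spec, acc = proportion_stats(t)

    def ci(numer: int, denom: int) -> tuple[float, float]:
        if denom == 0:
            return float("nan"), float("nan")
        return wilson_ci(numer, denom, level)

    k = cohens_kappa(t)
    return ConcordanceStats(
        table=t,
        sensitivity=sens,
        sensitivity_ci=ci(t.a, t.a + t.c),
        specificity=spec,
        specificity_ci=ci(t.d, t.b + t.d),
        accuracy=acc,
        accuracy_ci=ci(t.a + t.d, t.n),
        kappa=k,
        kappa_ci=kappa_ci(t, level, method=kappa_method),
        kappa_band=interpret_kappa(k),
    )


_STATUS_COLUMNS = {
    "GLIM": "glim_status",
    "SGA": "sga_status",
    "ESPEN2015": "espen_status",
    "ESPEN": "espen_status",
}


def concordance_report(
    dx_table: pd.DataFrame,
    test_criterion: str,
    ref_criterion: str,
    level: float = 0.95,
) -> ConcordanceStats:
    """Agreement of one criterion against another on a diagnosis table.

    ``dx_table`` is the output of :func:`malnutdx.diagnostics.diagnose_all`;
    criteria are named GLIM / SGA / ESPEN2015 (or raw status column names).
    """

    def col(criterion: str) -> str:
        return _STATUS_COLUMNS.get(criterion.upper().replace(" ", ""), criterion)

    test = dx_table[col(test_criterion)].astype(bool).to_numpy()
    ref = dx_table[col(ref_criterion)].astype(bool).to_numpy()
    t = build_confusion(test, ref, label=f"{test_criterion} vs {ref_criterion}")
    return stats_from_table(t, level)
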