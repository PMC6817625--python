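"""Generic statistics reported alongside the path model: correlations,
paired comparisons, and a two-factor GLM with partial eta-squared."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "CorrelationResult",
    "AnovaTerm",
    "AnovaResult",
    "pearson_with_ci",
    "kendall_tau_b",
    "paired_t_test",
    "two_way_anova_partial_eta",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "kendall_b"
    estimate: float
    n: int
    p: float
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if abs(self.estimate) > 1 + 1e-12:
            raise ValueError(f"|estimate| > 1: {self.estimate}")
        if self.ci is not None and not (self.ci[0] - 1e-12 <= self.estimate <= self.ci[1] + 1e-12):
            raise ValueError(f"ci {self.ci} does not bracket estimate {self.estimate}")


@dataclass(frozen=True)
class AnovaTerm:
    F: float
    df: tuple[float, float]
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class AnovaResult:
    terms: dict[str, AnovaTerm]
    emmeans: dict[str, dict[str, float]]  # factor -> level -> estimated marginal mean
    n: int


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    keep = np.isfinite(x) & np.isfinite(y)
    return x[keep], y[keep]


def pearson_with_ci(x, y, conf: float = 0.95) -> CorrelationResult:
    """Product-moment correlation with a t-based two-sided p and Fisher-z CI."""
    x, y = _clean_pair(x, y)
    n = len(x)
    if n < 4:
        raise ValueError(f"need n >= 4, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if abs(r) < 1.0:
        z = math.atanh(r)
        half = sps.norm.ppf(0.5 + conf / 2.0) / math.sqrt(n - 3)
        ci = (math.tanh(z - half), math.tanh(z + half))
    else:
        ci = (r, r)
    return CorrelationResult("pearson", r, n, float(p), ci)


def kendall_tau_b(x, y) -> CorrelationResult:
    """Kendall's tau-b (tie-corrected) with a normal-approximation p."""
    x, y = _clean_pair(x, y)
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("all-tied input; tau undefined")
    res = sps.kendalltau(x, y, variant="b", method="asymptotic")
    return CorrelationResult("kendall_b", float(res.statistic), n, float(res.pvalue))


def paired_t_test(a, b) -> tuple[float, int, float]:
    """Two-sided paired t-test; returns (t, df, p)."""
    a, b = _clean_pair(a, b)
    n = len(a)
    if n < 2:
        raise ValueError(f"need n >= 2 pairs, got {n}")
    d = a - b
    if d.std(ddof=1) == 0:
        if np.all(d == 0):
            return 0.0, n - 1, 1.0
        raise ValueError("zero-variance nonzero differences; t undefined")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), n - 1, float(res.pvalue)


def two_way_anova_partial_eta(
    data: pd.DataFrame,
    dv: str,
    factor_a: str = "sex",
    factor_b: str = "country",
    include_interaction: bool = True,
) -> AnovaResult:
    """Type-III two-way ANOVA with sum-to-zero contrasts.

    Per term: F, (df_effect, df_error), p and partial eta-squared
    SS_effect / (SS_effect + SS_error). Estimated marginal means are cell
    means averaged with equal weight over the other factor's levels.
    """
    cols = data[[dv, factor_a, factor_b]].dropna()
    n = len(cols)
    counts = cols.groupby([factor_a, factor_b], observed=True).size().unstack(fill_value=0)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("each factor needs >= 2 observed levels")
    if (counts == 0).any().any():
        empty = [
            (a, b)
            for a in counts.index
            for b in counts.columns
            if counts.loc[a, b] == 0
        ]
        raise ValueError(f"empty design cells: {empty}")

    rhs = f"C({factor_a}, Sum) * C({factor_b}, Sum)" if include_interaction else (
        f"C({factor_a}, Sum) + C({factor_b}, Sum)"
    )
    model = smf.ols(f"Q('{dv}') ~ {rhs}", data=cols).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    table = sm.stats.anova_lm(model, typ=3)
    ss_err = float(table.loc["Residual", "sum_sq"])
    df_err = float(table.loc["Residual", "df"])

    def _label(term: str) -> str:
        return (
            term.replace(f"C({factor_a}, Sum)", factor_a)
            .replace(f"C({factor_b}, Sum)", factor_b)
            .replace(":", " x ")
        )

    terms: dict[str, AnovaTerm] = {}
    for term in table.index:
        if term in ("Residual", "Intercept"):
            continue
        ss = float(table.loc[term, "sum_sq"])
        terms[_label(term)] = AnovaTerm(
            F=float(table.loc[term, "F"]),
            df=(float(table.loc[term, "df"]), df_err),
            p=float(table.loc[term, "PR(>F)"]),
            partial_eta_sq=ss / (ss + ss_err),
        )

    cell_means = cols.groupby([factor_a, factor_b], observed=True)[dv].mean().unstack()
    emmeans = {
        factor_a: {str(a): float(cell_means.loc[a].mean()) for a in cell_means.index},
        factor_b: {str(b): float(cell_means[b].mean()) for b in cell_means.columns},
    }
    return AnovaResult(terms=terms, emmeans=emmeans, n=n)
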