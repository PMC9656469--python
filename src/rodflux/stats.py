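"""The study's statistical layer.

Two-sample t tests (from raw samples or from printed mean/SEM/n summaries,
pooled-variance Student's t by default), two-way ANOVA with Bonferroni
post-hoc comparisons, one-way ANCOVA with a baseline covariate and a
slope-homogeneity pretest, and the ordinary regression slope t test. All p
values are two-tailed; all functions are pure functions of their inputs.

The heavy lifting is delegated to scipy.stats and statsmodels; this module
fixes the conventions (pooled variance, sum-of-squares type, nested-model F
for the ANCOVA) and packages results in small typed containers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "GroupSummary",
    "TTestResult",
    "AnovaResult",
    "AncovaResult",
    "PosthocComparison",
    "RegressionSlopeResult",
    "t_from_summary",
    "t_test",
    "two_way_anova",
    "bonferroni_posthoc",
    "ancova_one_way",
    "regression_slope_test",
]


@dataclass(frozen=True)
class GroupSummary:
    """Printed-style group summary: mean, SEM and sample size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summaries require n >= 2")
        if self.sem < 0:
            raise ValueError("SEM must be non-negative")

    @property
    def sd(self) -> float:
        return self.sem * np.sqrt(self.n)

    @classmethod
    def from_samples(cls, x: Sequence[float]) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("need at least two observations")
        return cls(mean=float(x.mean()), sem=float(x.std(ddof=1) / np.sqrt(x.size)), n=int(x.size))


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    method: str  # "pooled" or "welch"
    degenerate: bool = False  # both groups had (near) zero variance

    def summary(self) -> str:
        return f"t = {self.t:.5f} with {self.df:g} df: p = {self.p:.5g} ({self.method})"


def t_from_summary(g1: GroupSummary, g2: GroupSummary, method: str = "pooled") -> TTestResult:
    """Two-sample two-tailed t test from (mean, SEM, n) summaries."""
    if method not in ("pooled", "welch"):
        raise ValueError("method must be 'pooled' or 'welch'")
    res = sp_stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=(method == "pooled")
    )
    if method == "pooled":
        df = g1.n + g2.n - 2
    else:
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    degenerate = g1.sd == 0 and g2.sd == 0
    t = float(res.statistic)
    p = float(res.pvalue)
    if degenerate:
        t = 0.0 if g1.mean == g2.mean else float(np.sign(g1.mean - g2.mean)) * float("inf")
        p = 1.0 if g1.mean == g2.mean else 0.0
    return TTestResult(t=t, df=float(df), p=p, method=method, degenerate=degenerate)


def t_test(x1: Sequence[float], x2: Sequence[float], method: str = "pooled") -> TTestResult:
    """Two-sample two-tailed t test on raw samples.

    Identical to ``t_from_summary`` applied to the groups' computed summaries.
    """
    return t_from_summary(GroupSummary.from_samples(x1), GroupSummary.from_samples(x2), method)


@dataclass(frozen=True)
class AnovaEffect:
    f: float
    df_num: float
    df_den: float
    p: float


@dataclass
class AnovaResult:
    """Two-way ANOVA: per-effect F statistics plus the residual mean square."""

    effects: dict[str, AnovaEffect]
    residual_ms: float
    residual_df: float
    ss_type: int
    table: pd.DataFrame  # full anova_lm table

    def summary(self) -> str:
        lines = [f"Two-way ANOVA (type {self.ss_type} sums of squares)"]
        for name, e in self.effects.items():
            lines.append(f"  {name}: F = {e.f:.5f} with {e.df_num:g}, {e.df_den:g} df: p = {e.p:.5g}")
        lines.append(f"  residual MS = {self.residual_ms:.5g} on {self.residual_df:g} df")
        return "\n".join(lines)


def two_way_anova(
    table: pd.DataFrame,
    value: str = "value",
    factor_a: str = "genotype",
    factor_b: str = "k_level",
    ss_type: int = 2,
    interaction: bool = True,
) -> AnovaResult:
    """Two-way ANOVA of ``value`` on two categorical factors.

    Type II sums of squares by default (robust to mild imbalance); the type
    is recorded in the result. Observations are treated as independent.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    data = table[[value, factor_a, factor_b]].dropna().copy()
    if data[factor_a].nunique() < 2 and data[factor_b].nunique() < 2:
        raise ValueError("both factors are constant; nothing to test")
    # a factor collapsed to one level reduces the design to a one-way ANOVA
    for fac, other in ((factor_a, factor_b), (factor_b, factor_a)):
        if data[fac].nunique() < 2:
            fit = smf.ols(f"{value} ~ C({other})", data=data).fit()
            aov = sm.stats.anova_lm(fit, typ=1)
            resid_df = float(aov.loc["Residual", "df"])
            resid_ms = float(aov.loc["Residual", "sum_sq"] / resid_df)
            eff = AnovaEffect(
                f=float(aov.loc[f"C({other})", "F"]),
                df_num=float(aov.loc[f"C({other})", "df"]),
                df_den=resid_df,
                p=float(aov.loc[f"C({other})", "PR(>F)"]),
            )
            return AnovaResult(
                effects={other: eff}, residual_ms=resid_ms, residual_df=resid_df, ss_type=1, table=aov
            )
    counts = data.groupby([factor_a, factor_b], observed=True).size()
    expected_cells = data[factor_a].nunique() * data[factor_b].nunique()
    if len(counts) < expected_cells:
        raise ValueError("design has empty cells; every factor combination needs observations")

    op = "*" if interaction else "+"
    formula = f"{value} ~ C({factor_a}) {op} C({factor_b})"
    fit = smf.ols(formula, data=data).fit()
    aov = sm.stats.anova_lm(fit, typ=ss_type)
    effects: dict[str, AnovaEffect] = {}
    resid_df = float(aov.loc["Residual", "df"])
    resid_ms = float(aov.loc["Residual", "sum_sq"] / resid_df)
    rename = {f"C({factor_a})": factor_a, f"C({factor_b})": factor_b, f"C({factor_a}):C({factor_b})": "interaction"}
    for row, name in rename.items():
        if row in aov.index:
            effects[name] = AnovaEffect(
                f=float(aov.loc[row, "F"]),
                df_num=float(aov.loc[row, "df"]),
                df_den=resid_df,
                p=float(aov.loc[row, "PR(>F)"]),
            )
    return AnovaResult(effects=effects, residual_ms=resid_ms, residual_df=resid_df, ss_type=ss_type, table=aov)


@dataclass(frozen=True)
class PosthocComparison:
    label: str
    diff: float
    t: float
    df: float
    p_raw: float
    p_adjusted: float


def bonferroni_posthoc(
    table: pd.DataFrame,
    anova: AnovaResult,
    comparisons: Sequence[tuple[tuple, tuple]],
    value: str = "value",
    factors: tuple[str, str] = ("genotype", "k_level"),
) -> list[PosthocComparison]:
    """Bonferroni-corrected cell-mean comparisons on the ANOVA residual MS.

    Each comparison is a pair of factor-level tuples identifying two design
    cells. The per-comparison t uses the pooled residual mean square; raw p
    values are multiplied by the number of comparisons and capped at 1.
    """
    k = len(comparisons)
    out = []
    for (a, b) in comparisons:
        cells = []
        for levels in (a, b):
            mask = np.ones(len(table), dtype=bool)
            for fac, lev in zip(factors, levels):
                mask &= table[fac].to_numpy() == lev
            vals = table.loc[mask, value].to_numpy(dtype=float)
            if vals.size == 0:
                raise ValueError(f"comparison references an empty cell: {dict(zip(factors, levels))}")
            cells.append(vals)
        m1, m2 = cells[0].mean(), cells[1].mean()
        se = np.sqrt(anova.residual_ms * (1.0 / len(cells[0]) + 1.0 / len(cells[1])))
        t = (m1 - m2) / se
        p_raw = 2.0 * sp_stats.t.sf(abs(t), anova.residual_df)
        out.append(
            PosthocComparison(
                label=f"{a} vs {b}",
                diff=float(m1 - m2),
                t=float(t),
                df=anova.residual_df,
                p_raw=float(p_raw),
                p_adjusted=float(min(1.0, k * p_raw)),
            )
        )
    return out


@dataclass
class AncovaResult:
    """One-way ANCOVA with a single covariate.

    The group effect is the nested-model F comparing y ~ group + covariate
    against y ~ covariate. The slope-homogeneity pretest compares
    y ~ group * covariate against the additive model.
    """

    f: float
    df_num: float
    df_den: float
    p: float
    adjusted_means: dict
    common_slope: float
    homogeneity_f: float
    homogeneity_df: tuple[float, float]
    homogeneity_p: float

    def summary(self) -> str:
        adj = ", ".join(f"{g}: {m:.4g}" for g, m in self.adjusted_means.items())
        return (
            f"One-way ANCOVA: group F = {self.f:.5f} with {self.df_num:g}, {self.df_den:g} df: p = {self.p:.5g}\n"
            f"  adjusted means: {adj}\n"
            f"  common slope = {self.common_slope:.5g}\n"
            f"  slope homogeneity: F = {self.homogeneity_f:.5f} with "
            f"{self.homogeneity_df[0]:g}, {self.homogeneity_df[1]:g} df: p = {self.homogeneity_p:.5g}"
        )


def _nested_f(rss_reduced: float, rss_full: float, df_reduced: float, df_full: float) -> tuple[float, float, float]:
    df_num = df_reduced - df_full
    f = ((rss_reduced - rss_full) / df_num) / (rss_full / df_full)
    p = float(sp_stats.f.sf(f, df_num, df_full))
    return float(f), float(df_num), p


def ancova_one_way(
    y: Sequence[float],
    group: Sequence,
    covariate: Sequence[float],
    force_slope: float | None = None,
) -> AncovaResult:
    """Group effect on ``y`` adjusted for one covariate, with slope pretest.

    ``force_slope`` fixes the covariate slope instead of estimating it
    (the covariate contribution is subtracted from ``y`` and the covariate
    dropped from the models); with ``force_slope=0`` the group F reduces
    exactly to the one-way ANOVA F.
    """
    import statsmodels.formula.api as smf

    data = pd.DataFrame({"y": np.asarray(y, float), "g": np.asarray(group), "x": np.asarray(covariate, float)})
    if data["g"].nunique() < 2:
        raise ValueError("need at least two groups")
    if np.allclose(data["x"].var(ddof=0), 0.0):
        raise ValueError("covariate is constant; ANCOVA is undefined")

    if force_slope is not None:
        data = data.assign(y=data["y"] - force_slope * data["x"])
        full = smf.ols("y ~ C(g)", data=data).fit()
        reduced = smf.ols("y ~ 1", data=data).fit()
        f, df_num, p = _nested_f(reduced.ssr, full.ssr, reduced.df_resid, full.df_resid)
        adjusted = {
            g: float(sub["y"].mean()) for g, sub in data.groupby("g", observed=True)
        }
        return AncovaResult(
            f=f,
            df_num=df_num,
            df_den=float(full.df_resid),
            p=p,
            adjusted_means=adjusted,
            common_slope=float(force_slope),
            homogeneity_f=float("nan"),
            homogeneity_df=(float("nan"), float("nan")),
            homogeneity_p=float("nan"),
        )

    full = smf.ols("y ~ C(g) + x", data=data).fit()
    reduced = smf.ols("y ~ x", data=data).fit()
    interact = smf.ols("y ~ C(g) * x", data=data).fit()

    f, df_num, p = _nested_f(reduced.ssr, full.ssr, reduced.df_resid, full.df_resid)
    hf, hdf_num, hp = _nested_f(full.ssr, interact.ssr, full.df_resid, interact.df_resid)

    slope = float(full.params["x"])
    grand_x = float(data["x"].mean())
    adjusted = {
        g: float(sub["y"].mean() - slope * (sub["x"].mean() - grand_x))
        for g, sub in data.groupby("g", observed=True)
    }
    return AncovaResult(
        f=f,
        df_num=df_num,
        df_den=float(full.df_resid),
        p=p,
        adjusted_means=adjusted,
        common_slope=slope,
        homogeneity_f=hf,
        homogeneity_df=(hdf_num, float(interact.df_resid)),
        homogeneity_p=hp,
    )


@dataclass(frozen=True)
class RegressionSlopeResult:
    slope: float
    se: float
    t: float
    df: int
    p: float
    intercept: float
    exact: bool = False  # residuals numerically zero: t reported as +/- inf

    def summary(self) -> str:
        return f"slope = {self.slope:.5g} +/- {self.se:.5g}; t = {self.t:.5f} with {self.df} df: p = {self.p:.5g}"


def regression_slope_test(x: Sequence[float], y: Sequence[float]) -> RegressionSlopeResult:
    """OLS slope with its classical SE and the two-tailed t test against 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 points")
    if np.allclose(x.var(ddof=0), 0.0):
        raise ValueError("zero variance in x; slope is undefined")
    res = sp_stats.linregress(x, y)
    df = n - 2
    if res.stderr == 0.0:  # exact line
        t = float(np.sign(res.slope)) * float("inf") if res.slope != 0 else 0.0
        p = 0.0 if res.slope != 0 else 1.0
        return RegressionSlopeResult(float(res.slope), 0.0, t, df, p, float(res.intercept), exact=True)
    t = res.slope / res.stderr
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    return RegressionSlopeResult(float(res.slope), float(res.stderr), float(t), df, float(p), float(res.intercept))
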