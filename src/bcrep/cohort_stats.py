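"""Cohort-level statistics over repertoire metrics.

Per-diet ordinary least squares of each metric over age, two-way
fixed-effects ANOVA (age x diet, with interaction) between diet pairs,
two-sided Mann-Whitney U tests between diets at each time point (exact
for small groups) with Bonferroni correction, and Spearman correlation of
each metric with the macromorbidity index and its neoplastic and
non-neoplastic components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

__all__ = [
    "RegressionResult",
    "AnovaResult",
    "StatResult",
    "bonferroni",
    "age_regression",
    "two_way_anova",
    "timepoint_test",
    "morbidity_correlation",
    "build_metric_table",
    "regression_table",
    "anova_table",
    "timepoint_table",
]

#: Exact Mann-Whitney enumeration up to this per-group size (the study's
#: n = 5 design makes the exact null distribution mandatory).
EXACT_MW_MAX_N = 8


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * number of simultaneous tests)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, float(p) * n_tests)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    pvalue: float
    rvalue: float
    n: int


def age_regression(values, ages) -> RegressionResult:
    """OLS of a metric on age within one diet; two-sided slope p-value."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(ages, dtype=float)
    if len(y) != len(x):
        raise ValueError("values and ages differ in length")
    if len(y) < 3:
        raise ValueError("need >= 3 points for an age regression")
    if len(np.unique(x)) < 2:
        raise ValueError("all ages equal: slope is undefined")
    res = stats.linregress(x, y)
    return RegressionResult(
        float(res.slope), float(res.intercept), float(res.pvalue), float(res.rvalue), len(y)
    )


@dataclass(frozen=True)
class AnovaResult:
    p_age: float
    p_diet: float
    p_interaction: float
    n: int


def two_way_anova(values, ages, diets) -> AnovaResult:
    """Fixed-effects two-factor ANOVA with interaction for two diet groups."""
    df = pd.DataFrame(
        {
            "metric": np.asarray(values, dtype=float),
            "age": pd.Categorical(ages),
            "diet": pd.Categorical(diets),
        }
    )
    if df["diet"].nunique() != 2:
        raise ValueError("two-way ANOVA compares exactly two diet groups")
    if df["age"].nunique() < 2:
        raise ValueError("need >= 2 ages")
    cells = df.groupby(["age", "diet"], observed=False).size()
    bad = cells[cells < 2]
    if len(bad):
        raise ValueError(
            "cells with fewer than 2 replicates: "
            + ", ".join(f"(age={a}, diet={d})" for a, d in bad.index)
        )
    model = smf.ols("metric ~ C(age) * C(diet)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return AnovaResult(
        p_age=float(table.loc["C(age)", "PR(>F)"]),
        p_diet=float(table.loc["C(diet)", "PR(>F)"]),
        p_interaction=float(table.loc["C(age):C(diet)", "PR(>F)"]),
        n=len(df),
    )


@dataclass(frozen=True)
class StatResult:
    metric: str
    contrast: str
    statistic: float
    pvalue: float
    p_adjusted: float
    n1: int
    n2: int
    method: str


def timepoint_test(
    group_a,
    group_b,
    n_tests: int = 1,
    metric: str = "",
    contrast: str = "",
) -> StatResult:
    """Two-sided Mann-Whitney U between two diet groups at one time point.

    The exact null distribution is enumerated when both groups have at
    most 8 values and no cross-group ties; otherwise the tie-corrected
    normal approximation is used. The Bonferroni adjustment multiplies by
    ``n_tests``, the number of simultaneous tests in the family.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    ties = len(np.intersect1d(a, b)) > 0 or len(np.unique(np.r_[a, b])) < len(a) + len(b)
    exact = max(len(a), len(b)) <= EXACT_MW_MAX_N and not ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    p = float(res.pvalue)
    return StatResult(
        metric=metric,
        contrast=contrast,
        statistic=float(res.statistic),
        pvalue=p,
        p_adjusted=bonferroni(p, n_tests),
        n1=len(a),
        n2=len(b),
        method="exact" if exact else "asymptotic",
    )


def build_metric_table(
    profiles: pd.DataFrame, meta: pd.DataFrame, morbidity: pd.DataFrame
) -> pd.DataFrame:
    """Join per-sample metrics with sample metadata and per-mouse morbidity.

    One row per sample; join mismatches are reported, never silently
    dropped.
    """
    if profiles["sample_id"].duplicated().any():
        raise ValueError("metric table must have one row per sample")
    merged = profiles.merge(meta, on="sample_id", how="left", validate="one_to_one")
    missing_meta = merged["mouse_id"].isna()
    if missing_meta.any():
        warnings.warn(
            f"{int(missing_meta.sum())} sample(s) without metadata: "
            f"{merged.loc[missing_meta, 'sample_id'].tolist()}",
            stacklevel=2,
        )
    merged = merged.merge(morbidity, on="mouse_id", how="left")
    missing_morb = merged["macromorbidity"].isna() & ~missing_meta
    if missing_morb.any():
        warnings.warn(
            f"{int(missing_morb.sum())} sample(s) without a pathology record: "
            f"{merged.loc[missing_morb, 'sample_id'].tolist()}",
            stacklevel=2,
        )
    return merged


OUTCOMES = ("macromorbidity", "neoplasia_grade", "non_neoplastic_burden")


def morbidity_correlation(
    table: pd.DataFrame,
    metrics: list[str],
    outcomes: tuple[str, ...] = OUTCOMES,
    min_pairs: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of each metric with each morbidity outcome.

    Mid-rank ties; the Bonferroni family is the set of defined tests
    within one outcome panel. Metrics constant over the paired
    observations (or with fewer than ``min_pairs`` pairs) are flagged
    undefined and excluded from the family. Both the Spearman rho^2 and
    the OLS R^2 are emitted as variance-explained summaries.
    """
    rows = []
    for outcome in outcomes:
        panel = []
        for metric in metrics:
            sub = table[[metric, outcome]].dropna()
            x, y = sub[metric].to_numpy(float), sub[outcome].to_numpy(float)
            defined = (
                len(sub) >= min_pairs and np.ptp(x) > 0 and np.ptp(y) > 0
            )
            if defined:
                rho, p = stats.spearmanr(x, y)
                r2 = float(stats.linregress(x, y).rvalue ** 2)
                panel.append(
                    {
                        "metric": metric,
                        "outcome": outcome,
                        "rho": float(rho),
                        "pvalue": float(p),
                        "rho_squared": float(rho) ** 2,
                        "r_squared_linear": r2,
                        "n": len(sub),
                        "defined": True,
                    }
                )
            else:
                panel.append(
                    {
                        "metric": metric,
                        "outcome": outcome,
                        "rho": np.nan,
                        "pvalue": np.nan,
                        "rho_squared": np.nan,
                        "r_squared_linear": np.nan,
                        "n": len(sub),
                        "defined": False,
                    }
                )
        family = sum(r["defined"] for r in panel)
        for r in panel:
            r["p_adjusted"] = bonferroni(r["pvalue"], family) if r["defined"] else np.nan
            r["family_size"] = family
        rows.extend(panel)
    return pd.DataFrame(rows)


def regression_table(
    table: pd.DataFrame, metrics: list[str], diets: tuple[str, ...] = ("AL", "DR")
) -> pd.DataFrame:
    """Per-diet age regressions for every metric."""
    rows = []
    for diet in diets:
        sub = table[table["diet"] == diet]
        for metric in metrics:
            pts = sub[[metric, "age_months"]].dropna()
            if len(pts) < 3 or pts["age_months"].nunique() < 2:
                continue
            res = age_regression(pts[metric], pts["age_months"])
            rows.append(
                {
                    "metric": metric,
                    "diet": diet,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "pvalue": res.pvalue,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def anova_table(
    table: pd.DataFrame,
    metrics: list[str],
    diet_pairs: tuple[tuple[str, str], ...] = (("AL", "DR"),),
) -> pd.DataFrame:
    rows = []
    for d1, d2 in diet_pairs:
        sub = table[table["diet"].isin([d1, d2])]
        for metric in metrics:
            pts = sub[[metric, "age_months", "diet"]].dropna()
            try:
                res = two_way_anova(pts[metric], pts["age_months"], pts["diet"])
            except ValueError:
                continue
            rows.append(
                {
                    "metric": metric,
                    "diet_pair": f"{d1}_vs_{d2}",
                    "p_age": res.p_age,
                    "p_diet": res.p_diet,
                    "p_interaction": res.p_interaction,
                    "n": res.n,
                }
            )
    return pd.DataFrame(rows)


def timepoint_table(
    table: pd.DataFrame,
    metrics: list[str],
    diet_pairs: tuple[tuple[str, str], ...] = (("AL", "DR"),),
) -> pd.DataFrame:
    """All metric x age x diet-pair Mann-Whitney tests, Bonferroni over the family."""
    jobs = []
    for d1, d2 in diet_pairs:
        for age in sorted(table["age_months"].dropna().unique()):
            at = table[table["age_months"] == age]
            ga = at.loc[at["diet"] == d1]
            gb = at.loc[at["diet"] == d2]
            for metric in metrics:
                a = ga[metric].dropna()
                b = gb[metric].dropna()
                if len(a) >= 2 and len(b) >= 2:
                    jobs.append((metric, d1, d2, age, a, b))
    rows = []
    for metric, d1, d2, age, a, b in jobs:
        res = timepoint_test(
            a, b, n_tests=len(jobs), metric=metric,
            contrast=f"{d1}_vs_{d2}@{age}m",
        )
        rows.append(
            {
                "metric": metric,
                "diet_pair": f"{d1}_vs_{d2}",
                "age_months": age,
                "U": res.statistic,
                "pvalue": res.pvalue,
                "p_adjusted": res.p_adjusted,
                "method": res.method,
                "n1": res.n1,
                "n2": res.n2,
                "family_size": len(jobs),
            }
        )
    return pd.DataFrame(rows)
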