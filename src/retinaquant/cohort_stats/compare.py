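"""Raw and covariate-adjusted group comparisons of eye-level parameters."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ..phenotyping.contingency import chi2_test


@dataclass
class GroupComparison:
    parameter: str
    test: str
    p_value: float
    statistic: float
    summaries: dict[str, tuple[float, float, int]] = field(default_factory=dict)


@dataclass
class AdjustedComparison:
    parameter: str
    covariates: list[str]
    overall_p: float
    pairwise_p: dict[tuple[str, str], float]
    adjusted_means: dict[str, float]


def _group_values(
    records: pd.DataFrame, parameter: str, grouping: str
) -> dict[str, np.ndarray]:
    out = {}
    for g, sub in records.groupby(grouping, sort=False):
        out[str(g)] = np.asarray(sub[parameter], dtype=float)
    if len(out) < 2 or any(len(v) < 2 for v in out.values()):
        raise ValueError("need >= 2 groups with >= 2 eyes each")
    return out


def group_compare(
    records: pd.DataFrame,
    parameter: str,
    grouping: str = "group",
    test: str = "auto",
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Between-group test of one parameter with per-group mean +/- SD.

    ``auto`` picks the t-test (two groups) or one-way ANOVA (more) when
    every group passes a Shapiro-Wilk normality screen, Kruskal-Wallis
    otherwise, and chi-squared for non-numeric (categorical) parameters.
    """
    if test not in ("auto", "t", "anova", "kw", "chi2"):
        raise ValueError(f"unknown test {test!r}")
    is_categorical = not pd.api.types.is_numeric_dtype(records[parameter])
    if test == "chi2" or (test == "auto" and is_categorical):
        table = pd.crosstab(records[parameter], records[grouping])
        stat, p = chi2_test(np.asarray(table).T[:2]) if table.shape[0] == 2 else (
            stats.chi2_contingency(np.asarray(table), correction=False)[:2]
        )
        return GroupComparison(parameter, "chi2", float(p), float(stat))

    groups = _group_values(records, parameter, grouping)
    values = list(groups.values())
    if any(np.std(v) == 0 for v in values) and all(
        np.std(v) == 0 for v in values
    ):
        raise ValueError(f"parameter {parameter!r} is constant within every group")
    if test == "auto":
        # a zero-variance group fails the normality screen outright
        normal = all(
            np.std(v) > 0 and stats.shapiro(v[:5000]).pvalue >= normality_alpha
            for v in values
        )
        test = ("t" if len(values) == 2 else "anova") if normal else "kw"
    if test == "t":
        if len(values) != 2:
            raise ValueError("t-test requires exactly two groups")
        stat, p = stats.ttest_ind(values[0], values[1], equal_var=False)
    elif test == "anova":
        stat, p = stats.f_oneway(*values)
    else:
        stat, p = stats.kruskal(*values)
    summaries = {
        g: (float(v.mean()), float(v.std(ddof=1)), len(v)) for g, v in groups.items()
    }
    return GroupComparison(parameter, test, float(p), float(stat), summaries)


def adjusted_group_compare(
    records: pd.DataFrame,
    parameter: str,
    grouping: str = "group",
    covariates: tuple[str, ...] = ("age", "dm_duration"),
    cluster: str = "subject_id",
) -> AdjustedComparison:
    """Covariate-adjusted group contrasts via a clustered linear model.

    Regresses the parameter on group indicators plus covariates with an
    exchangeable estimating-equation fit clustered on participant; reports
    the overall Wald test of the group terms, all pairwise contrasts, and
    covariate-adjusted group means at covariate averages.
    """
    levels = list(pd.unique(records[grouping]))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    y = np.asarray(records[parameter], dtype=float)
    X = pd.DataFrame(index=records.index)
    for level in levels[1:]:
        X[f"g_{level}"] = (records[grouping] == level).astype(float)
    for cov in covariates:
        col = np.asarray(records[cov], dtype=float)
        if np.any(~np.isfinite(col)):
            raise ValueError(f"covariate {cov!r} contains non-finite values")
        X[cov] = col
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X.values]))
    if rank < X.shape[1] + 1:
        raise ValueError("collinear design (group indicators + covariates)")
    exog = sm.add_constant(X, has_constant="add")
    fit = sm.GEE(
        y,
        exog,
        groups=np.asarray(records[cluster]),
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    ).fit()

    group_terms = [f"g_{level}" for level in levels[1:]]
    constraint = " = 0, ".join(group_terms) + " = 0"
    overall_p = float(np.squeeze(fit.wald_test(constraint, scalar=True).pvalue))

    params = fit.params
    cov = fit.cov_params()
    effects = {levels[0]: 0.0}
    for level in levels[1:]:
        effects[level] = float(params[f"g_{level}"])
    pairwise: dict[tuple[str, str], float] = {}
    for i, gi in enumerate(levels):
        for gj in levels[i + 1:]:
            vec = pd.Series(0.0, index=params.index)
            if gi != levels[0]:
                vec[f"g_{gi}"] = 1.0
            if gj != levels[0]:
                vec[f"g_{gj}"] -= 1.0
            diff = float(vec @ params)
            var = float(vec @ cov @ vec)
            z = diff / np.sqrt(var)
            pairwise[(gi, gj)] = float(2 * stats.norm.sf(abs(z)))
    cov_means = {c: float(np.mean(records[c])) for c in covariates}
    base = float(params["const"]) + sum(
        params[c] * cov_means[c] for c in covariates
    )
    adjusted_means = {g: base + effects[g] for g in levels}
    return AdjustedComparison(
        parameter=parameter,
        covariates=list(covariates),
        overall_p=overall_p,
        pairwise_p=pairwise,
        adjusted_means=adjusted_means,
    )
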