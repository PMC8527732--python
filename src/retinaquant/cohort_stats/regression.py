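"""Cluster-robust linear regression for eye-level outcomes.

All models are estimating-equation linear fits clustered on participant
(exchangeable working correlation, sandwich standard errors), so that the
two eyes of one participant do not count as independent observations.
Confidence intervals follow the printed-table convention
``coefficient +/- 1.96 x SE``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z_95 = 1.96

#: Predictors screened against the acuity outcome, in reporting order.
DEFAULT_PREDICTORS: tuple[str, ...] = (
    "age",
    "dm_duration",
    "etdrs_level",
    "eye",
    "vd_srcp",
    "vd_drcp",
    "faz_area_mm2",
    "rnfl_um",
    "gcl_ipl_um",
    "inl_um",
    "opl_um",
    "total_um",
)


@dataclass
class PredictorEstimate:
    name: str
    coefficient: float
    standard_error: float
    ci_lower: float
    ci_upper: float
    p_value: float


@dataclass
class RegressionResult:
    """One fitted clustered linear model."""

    outcome: str
    predictors: list[str]
    estimates: dict[str, PredictorEstimate]
    cluster_variable: str
    working_correlation: str = "exchangeable"
    n_observations: int = 0
    n_clusters: int = 0
    notes: dict = field(default_factory=dict)

    def coefficient(self, name: str) -> float:
        return self.estimates[name].coefficient

    def p_value(self, name: str) -> float:
        return self.estimates[name].p_value

    def significant(self, alpha: float = 0.05) -> list[str]:
        return [
            n for n in self.predictors if self.estimates[n].p_value < alpha
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": e.name,
                "coefficient": e.coefficient,
                "standard_error": e.standard_error,
                "ci_lower": e.ci_lower,
                "ci_upper": e.ci_upper,
                "p_value": e.p_value,
            }
            for e in self.estimates.values()
        ]
        return pd.DataFrame(rows).set_index("predictor")


def _encode(records: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design columns: eye OD=0/OS=1; severity level ordinal 0/1/2."""
    X = pd.DataFrame(index=records.index)
    for col in columns:
        if col == "eye":
            X[col] = (records["eye"] == "OS").astype(float)
        elif col == "etdrs_level":
            mapping = {"20": 0.0, "35": 1.0, "43-53": 2.0}
            X[col] = records["etdrs_level"].astype(str).map(mapping)
            if X[col].isna().any():
                raise ValueError("unknown severity level in etdrs_level")
        else:
            X[col] = np.asarray(records[col], dtype=float)
    return X


def fit_clustered_lm(
    records: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    cluster: str = "subject_id",
) -> RegressionResult:
    """Gaussian estimating-equation fit of ``outcome`` on ``predictors``,
    clustered on ``cluster`` with exchangeable working correlation and
    robust standard errors."""
    if not predictors:
        raise ValueError("need at least one predictor")
    y = np.asarray(records[outcome], dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"outcome {outcome!r} contains non-finite values")
    X = _encode(records, list(predictors))
    for col in X.columns:
        if np.asarray(X[col]).std() == 0:
            raise ValueError(f"predictor {col!r} is constant")
    exog = sm.add_constant(X, has_constant="add")
    groups = records[cluster]
    model = sm.GEE(
        y,
        exog,
        groups=np.asarray(groups),
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    fit = model.fit()
    estimates: dict[str, PredictorEstimate] = {}
    for name in exog.columns:
        coef = float(fit.params[name])
        se = float(fit.bse[name])
        key = "intercept" if name == "const" else name
        estimates[key] = PredictorEstimate(
            name=key,
            coefficient=coef,
            standard_error=se,
            ci_lower=coef - Z_95 * se,
            ci_upper=coef + Z_95 * se,
            p_value=float(fit.pvalues[name]),
        )
    return RegressionResult(
        outcome=outcome,
        predictors=list(predictors),
        estimates=estimates,
        cluster_variable=cluster,
        n_observations=len(records),
        n_clusters=int(pd.Series(groups).nunique()),
    )


def univariate_screen(
    records: pd.DataFrame,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
    outcome: str = "bcva_logmar",
    cluster: str = "subject_id",
    alpha: float = 0.05,
) -> list[RegressionResult]:
    """One single-predictor clustered model per candidate; each result's
    ``notes['significant']`` records whether p < alpha."""
    results = []
    for predictor in predictors:
        res = fit_clustered_lm(records, outcome, [predictor], cluster)
        res.notes["significant"] = res.p_value(predictor) < alpha
        results.append(res)
    return results


def multivariate_model(
    records: pd.DataFrame,
    selected_predictors: list[str],
    outcome: str = "bcva_logmar",
    cluster: str = "subject_id",
    alpha: float = 0.05,
) -> RegressionResult:
    """Joint clustered model with backward elimination.

    Starting from ``selected_predictors``, the least-significant term with
    p >= alpha is dropped and the model refit until every retained term is
    significant.  If elimination empties the model, an intercept-only
    summary of the outcome is returned with a warning note.
    """
    if not selected_predictors:
        raise ValueError("need at least one selected predictor")
    current = list(selected_predictors)
    eliminated: list[str] = []
    while current:
        res = fit_clustered_lm(records, outcome, current, cluster)
        pvals = {n: res.p_value(n) for n in current}
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha:
            res.notes["eliminated"] = eliminated
            return res
        current.remove(worst)
        eliminated.append(worst)
    # intercept-only fallback
    y = np.asarray(records[outcome], dtype=float)
    mean = float(y.mean())
    se = float(y.std(ddof=1) / np.sqrt(len(y)))
    est = PredictorEstimate(
        name="intercept", coefficient=mean, standard_error=se,
        ci_lower=mean - Z_95 * se, ci_upper=mean + Z_95 * se, p_value=np.nan,
    )
    return RegressionResult(
        outcome=outcome,
        predictors=[],
        estimates={"intercept": est},
        cluster_variable=cluster,
        n_observations=len(records),
        n_clusters=int(records[cluster].nunique()),
        notes={"warning": "backward elimination removed every predictor",
               "eliminated": eliminated},
    )


def interaction_model(
    records: pd.DataFrame,
    base_predictors: tuple[str, ...] = ("age", "vd_drcp", "gcl_ipl_um"),
    interaction: tuple[str, str] = ("gcl_ipl_um", "vd_drcp"),
    outcome: str = "bcva_logmar",
    cluster: str = "subject_id",
) -> RegressionResult:
    """Add a product term of two mean-centred predictors to the joint model.

    The product column is built from sample-mean-centred copies of the two
    predictors (conditioning and interpretability; main effects keep their
    original scale).  The term is reported as ``"<a>:<b>"``.
    """
    a, b = interaction
    work = records.copy()
    ca = np.asarray(work[a], dtype=float)
    cb = np.asarray(work[b], dtype=float)
    product = (ca - ca.mean()) * (cb - cb.mean())
    if product.std() == 0:
        raise ValueError("interaction product term has zero variance")
    term = f"{a}:{b}"
    work[term] = product
    predictors = list(base_predictors)
    for p in (a, b):
        if p not in predictors:
            predictors.append(p)
    predictors.append(term)
    res = fit_clustered_lm(work, outcome, predictors, cluster)
    res.notes["interaction_term"] = term
    return res
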