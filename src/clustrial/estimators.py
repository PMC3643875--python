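"""Analysis strategies for a clustered individually randomised trial.

Three linear-model analyses of the treatment effect:

* :func:`fit_unadjusted` — outcome on treatment only (equivalently a pooled
  two-sample t-test);
* :func:`fit_fixed_effects` — outcome on treatment plus cluster indicator
  variables, appropriate when clusters contain patients from both arms;
* :func:`fit_cluster_summaries` — regression of per-cluster mean outcomes on
  the cluster's arm, the standard cluster-level analysis when clusters are
  nested within arms (where fixed effects would be confounded with treatment).

All return an :class:`AnalysisResult` with a two-sided t-test of beta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import SimulationError, validate_dataset as _validate

__all__ = [
    "AnalysisResult",
    "EstimationError",
    "ConfoundedDesignError",
    "DegenerateFitError",
    "fit_unadjusted",
    "fit_fixed_effects",
    "fit_cluster_summaries",
    "fit",
    "METHODS",
]

METHODS = ("unadjusted", "fixed_effects", "cluster_summaries")


class EstimationError(ValueError):
    """Dataset violates an estimator's preconditions."""


class ConfoundedDesignError(EstimationError):
    """Treatment is collinear with cluster indicators (every cluster pure).

    Raised by the fixed-effects analysis; use cluster-level summaries instead.
    """


class DegenerateFitError(EstimationError):
    """Zero residual variance: the t statistic is undefined."""


def validate_dataset(ds):
    try:
        return _validate(ds)
    except SimulationError as exc:
        raise EstimationError(str(exc)) from None


@dataclass(frozen=True)
class AnalysisResult:
    """Treatment-effect estimate with its two-sided t-test."""

    method: str
    beta_hat: float
    se: float
    df: int
    t_stat: float
    p_value: float


def _result(method: str, fit: "sm.regression.linear_model.RegressionResults") -> AnalysisResult:
    beta = float(fit.params["arm"])
    se = float(fit.bse["arm"])
    scale = max(float(np.abs(fit.fittedvalues).max()), 1.0)
    if not np.isfinite(se) or se <= 1e-10 * scale or fit.mse_resid <= (1e-12 * scale) ** 2:
        raise DegenerateFitError("zero residual variance; t statistic undefined")
    return AnalysisResult(
        method=method,
        beta_hat=beta,
        se=se,
        df=int(fit.df_resid),
        t_stat=float(fit.tvalues["arm"]),
        p_value=float(fit.pvalues["arm"]),
    )


def fit_unadjusted(ds: pd.DataFrame) -> AnalysisResult:
    """Linear regression of outcome on treatment assignment only.

    beta_hat is the difference in arm means; the test is the classical
    pooled-variance two-sample t-test with N − 2 degrees of freedom.
    """
    ds = validate_dataset(ds)
    if len(ds) < 3:
        raise EstimationError("need at least 3 observations")
    X = sm.add_constant(ds[["arm"]].astype(float))
    res = sm.OLS(ds["outcome"].to_numpy(float), X).fit()
    return _result("unadjusted", res)


def fit_fixed_effects(ds: pd.DataFrame) -> AnalysisResult:
    """Outcome on treatment plus cluster indicator variables.

    Only occupied clusters contribute indicators; residual degrees of freedom
    are N − J − 1 with J the number of occupied clusters.  Identification
    requires at least one cluster containing both arms.
    """
    ds = validate_dataset(ds)
    mixed = ds.groupby("cluster_id")["arm"].nunique()
    if (mixed < 2).all():
        raise ConfoundedDesignError(
            "every cluster is treated in a single arm; treatment is collinear with "
            "cluster indicators — use fit_cluster_summaries"
        )
    dummies = pd.get_dummies(ds["cluster_id"], prefix="cluster", drop_first=True, dtype=float)
    X = sm.add_constant(pd.concat([ds[["arm"]].astype(float), dummies], axis=1))
    res = sm.OLS(ds["outcome"].to_numpy(float), X).fit()
    return _result("fixed_effects", res)


def fit_cluster_summaries(ds: pd.DataFrame) -> AnalysisResult:
    """Regression of per-cluster mean outcomes on cluster arm.

    Each occupied cluster contributes its unweighted mean once; valid only
    when clusters are nested within arms, with at least two clusters per arm.
    Equivalent to a pooled two-sample t-test on the cluster means with
    J − 2 degrees of freedom.
    """
    ds = validate_dataset(ds)
    per = ds.groupby("cluster_id").agg(arm_n=("arm", "nunique"), arm=("arm", "first"), outcome=("outcome", "mean"))
    if (per["arm_n"] > 1).any():
        raise EstimationError("clusters not nested in arms: a cluster contains both arms")
    if (per["arm"].value_counts().reindex([0, 1], fill_value=0) < 2).any():
        raise EstimationError("need at least two clusters per arm")
    X = sm.add_constant(per[["arm"]].astype(float))
    res = sm.OLS(per["outcome"].to_numpy(float), X).fit()
    return _result("cluster_summaries", res)


def fit(ds: pd.DataFrame, method: str) -> AnalysisResult:
    """Dispatch to one of the three analyses by name."""
    try:
        f = {"unadjusted": fit_unadjusted, "fixed_effects": fit_fixed_effects, "cluster_summaries": fit_cluster_summaries}[method]
    except KeyError:
        raise EstimationError(f"unknown method {method!r}; choose from {METHODS}") from None
    return f(ds)
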