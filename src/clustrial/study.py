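"""The Monte-Carlo simulation study and the analytic power-loss curve.

The default experiment crosses three intraclass correlations (0, 0.05, 0.10),
three post-randomisation assignment mechanisms (equal, partial 80/20, one
arm) and four (therapists, patients) designs — (10, 100), (10, 200),
(50, 500), (50, 1000) — for 36 scenarios.  Each scenario is replicated 5000
times under a zero treatment effect and analysed twice: unadjusted, and
adjusted for therapist (fixed effects when therapists see both arms,
cluster-level summaries when each therapist sees one arm only).  The type I
error rate is the fraction of replicates rejecting at the nominal level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .design import VarianceDecomposition
from .estimators import EstimationError
from .simulate import Scenario

__all__ = [
    "Type1ErrorEstimate",
    "StudyTable",
    "default_grid",
    "adjusted_method_for",
    "estimate_type1",
    "run_study",
    "estimate_variance_decomposition",
    "power_loss",
    "DEFAULT_DESIGNS",
    "DEFAULT_ICCS",
    "DEFAULT_MECHANISMS",
]

DEFAULT_DESIGNS = ((10, 100), (10, 200), (50, 500), (50, 1000))
DEFAULT_ICCS = (0.0, 0.05, 0.10)
DEFAULT_MECHANISMS = ("equal", "partial_80_20", "one_arm")


@dataclass(frozen=True)
class Type1ErrorEstimate:
    """Monte-Carlo estimate of a type I error rate.

    ``mc_se`` is the binomial standard error sqrt(rate(1-rate)/reps) over the
    replicates that produced a valid fit; ``failed_fits`` counts the rest.
    """

    rate: float
    mc_se: float
    reps: int
    alpha: float
    failed_fits: int


def adjusted_method_for(mechanism: str) -> str:
    """The adjusted analysis matching an assignment mechanism.

    Cluster-level summaries when each therapist treats one arm only (fixed
    effects would be confounded with treatment); therapist fixed effects
    whenever therapists see both arms.
    """
    return "cluster_summaries" if mechanism == "one_arm" else "fixed_effects"


def _check_method(scenario: Scenario, method: str) -> None:
    if method == "fixed_effects" and scenario.mechanism == "one_arm":
        raise EstimationError(
            "fixed_effects is confounded under the one_arm mechanism; use cluster_summaries"
        )
    if method == "cluster_summaries" and scenario.mechanism != "one_arm":
        raise EstimationError(
            "cluster_summaries requires clusters nested in arms (one_arm mechanism)"
        )


def _estimate_from_stats(st: Dict[str, np.ndarray], reps: int, alpha: float) -> Type1ErrorEstimate:
    failed = int(st["failed"].sum())
    counted = reps - failed
    rej = int(np.nansum(st["p"] < alpha))
    rate = rej / counted if counted else float("nan")
    mc_se = float(np.sqrt(rate * (1.0 - rate) / counted)) if counted else float("nan")
    return Type1ErrorEstimate(rate=rate, mc_se=mc_se, reps=counted, alpha=alpha, failed_fits=failed)


def estimate_type1(
    scenario: Scenario,
    method: str,
    reps: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> Type1ErrorEstimate:
    """Type I error rate of one analysis method under one scenario.

    The scenario should have a zero treatment effect; replicate random
    streams are derived deterministically from the seed and the scenario.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    _check_method(scenario, method)
    st = _engine.run_replicates(scenario, [method], reps, seed)[method]
    return _estimate_from_stats(st, reps, alpha)


@dataclass(frozen=True)
class StudyTable:
    """Tidy results of a study run: one row per scenario × analysis method."""

    table: pd.DataFrame
    reps: int
    alpha: float
    seed: int

    def summary(self) -> Dict[str, float]:
        """Headline mean type I error rates, averaged over scenarios.

        Rates are proportions.  Keys cover the unadjusted analysis under
        non-ignorable clustering (one-arm and partial mechanisms at each
        non-zero ICC, averaged over the four designs), the pooled ignorable
        configurations, and the adjusted analyses pooled over scenarios with
        non-zero ICC (both over all 24 such scenarios and over the 16 with
        non-ignorable clustering).
        """
        t = self.table
        unadj = t[t["method"] == "unadjusted"]
        adj = t[t["method"] != "unadjusted"]
        ignorable = (t["icc"] == 0) | (t["mechanism"] == "equal")
        out: Dict[str, float] = {}
        for mech, tag in (("one_arm", "one_arm"), ("partial_80_20", "partial")):
            for icc in (0.05, 0.10):
                sel = unadj[(unadj["mechanism"] == mech) & (unadj["icc"] == icc)]
                out[f"unadjusted_{tag}_icc{int(icc * 100):02d}"] = float(sel["rate"].mean())
        out["unadjusted_ignorable"] = float(unadj[ignorable.loc[unadj.index]]["rate"].mean())
        out["adjusted_ignorable"] = float(adj[ignorable.loc[adj.index]]["rate"].mean())
        adj_pos = adj[adj["icc"] > 0]
        out["adjusted_icc_positive_24"] = float(adj_pos["rate"].mean())
        nonign = adj_pos[adj_pos["mechanism"] != "equal"]
        out["adjusted_nonignorable_16"] = float(nonign["rate"].mean())
        return out


def default_grid(seed: int = 0) -> List[Scenario]:
    """The 36-scenario grid: 4 designs × 3 ICCs × 3 mechanisms, null effect."""
    grid = []
    for j, n in DEFAULT_DESIGNS:
        for icc in DEFAULT_ICCS:
            for mech in DEFAULT_MECHANISMS:
                grid.append(
                    Scenario(n_clusters=j, n_patients=n, icc=icc, mechanism=mech, seed=seed)
                )
    return grid


def run_study(
    grid: Sequence[Scenario] | None = None,
    reps: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
) -> StudyTable:
    """Run the full study: both analyses for every scenario in the grid.

    Each scenario's replicate datasets are simulated once and analysed by
    both the unadjusted and the matching adjusted method.  Per-scenario
    errors are recorded in the ``error`` column rather than aborting the grid.
    """
    if grid is None:
        grid = default_grid(seed)
    rows = []
    for sc in grid:
        methods = ["unadjusted", adjusted_method_for(sc.mechanism)]
        try:
            st = _engine.run_replicates(sc, methods, reps, seed)
            for m in methods:
                est = _estimate_from_stats(st[m], reps, alpha)
                rows.append(_row(sc, m, est, alpha, None))
        except Exception as exc:  # record, keep going
            for m in methods:
                rows.append(_row(sc, m, None, alpha, str(exc)))
    return StudyTable(table=pd.DataFrame(rows), reps=reps, alpha=alpha, seed=seed)


def _row(sc: Scenario, method: str, est: Type1ErrorEstimate | None, alpha: float, error: str | None) -> dict:
    return {
        "n_clusters": sc.n_clusters,
        "n_patients": sc.n_patients,
        "icc": sc.icc,
        "mechanism": sc.mechanism,
        "method": method,
        "rate": est.rate if est else np.nan,
        "mc_se": est.mc_se if est else np.nan,
        "reps": est.reps if est else 0,
        "failed_fits": est.failed_fits if est else 0,
        "alpha": alpha,
        "error": error,
    }


def estimate_variance_decomposition(
    scenario: Scenario,
    method: str = "unadjusted",
    reps: int = 2000,
    seed: int = 0,
) -> VarianceDecomposition:
    """Empirical decomposition Var(beta_hat) = V0 + VE for one scenario.

    V0 is the mean model-based squared standard error over replicates (what
    the analysis believes the variance is); ``total`` is the empirical
    variance of beta_hat across replicates (what it actually is); VE is their
    difference.  VE > 0 means the model-based SE is biased downward.
    """
    if reps < 100:
        raise ValueError("need at least 100 replicates")
    _check_method(scenario, method)
    st = _engine.run_replicates(scenario, [method], reps, seed)[method]
    ok = ~st["failed"]
    beta = st["beta"][ok]
    se = st["se"][ok]
    v0 = float(np.mean(se**2))
    total = float(np.var(beta, ddof=1))
    return VarianceDecomposition(v0=v0, ve=total - v0, total=total)


def power_loss(icc: float, target_power: float = 0.80, alpha: float = 0.05) -> float:
    """Power forfeited by ignoring ignorable clustering with intraclass correlation `icc`.

    The adjusted analysis removes the between-cluster variance component and
    is powered at exactly ``target_power`` against residual variance
    ``1 − icc`` of the total; the unadjusted analysis tests the same contrast
    against the total variance.  Under the normal approximation its power is
    Φ((z_{1−α/2} + z_{power})·√(1−icc) − z_{1−α/2}), and the loss is the
    difference from ``target_power``.  Zero at icc = 0 and increasing in icc.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must lie in [0, 1)")
    if not 0.0 < target_power < 1.0 or not 0.0 < alpha < 1.0:
        raise ValueError("target_power and alpha must lie in (0, 1)")
    za = stats.norm.ppf(1.0 - alpha / 2.0)
    zb = stats.norm.ppf(target_power)
    attained = stats.norm.cdf((za + zb) * np.sqrt(1.0 - icc) - za)
    return float(target_power - attained)
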