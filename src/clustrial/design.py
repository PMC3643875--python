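"""Trial-design vocabulary and the non-ignorable clustering decision framework.

Clustering in an individually randomised trial is *non-ignorable* — it must be
modelled to obtain valid type I error rates — exactly when two correlations are
simultaneously non-zero: the intraclass correlation of outcomes (ICC) and the
within-cluster correlation of treatment assignments.  Writing the true variance
of the treatment-effect estimator as ``Var(beta_hat) = V0 + VE`` (``V0`` the
usual no-clustering variance, ``VE`` a signed clustering correction), the
unadjusted model-based variance is unbiased iff ``VE = 0``; ``VE`` shares the
sign of the assignment correlation when the ICC is positive, so a positive
assignment correlation biases the standard error downward (inflated type I
error) and a negative one biases it upward (conservative).

This module provides

* :class:`RandomisationScheme` and :func:`analytic_assignment_correlation` —
  the closed-form within-cluster assignment correlations (+1 for cluster
  randomisation, −1 for a 2×2 crossover, −1/(n−1) for stratified permuted
  blocks of size n, 0 for simple randomisation);
* :func:`empirical_assignment_correlation` — a pairwise estimator of the same
  quantity from observed (cluster, arm) data;
* :class:`ClusteringSourceSpec` and :func:`classify_source` — the decision
  rules that classify a declared source of clustering as ignorable or not,
  with the implied direction of standard-error bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "RandomisationScheme",
    "ClusteringSourceSpec",
    "IgnorabilityVerdict",
    "VarianceDecomposition",
    "analytic_assignment_correlation",
    "empirical_assignment_correlation",
    "classify_source",
    "DesignError",
]


class DesignError(ValueError):
    """Invalid trial-design description."""


_SCHEME_KINDS = frozenset(
    {"simple", "stratified_permuted_blocks", "cluster_randomised", "crossover_2x2"}
)
_TIMINGS = frozenset({"pre_randomisation", "post_randomisation"})
_ICC_ASSUMPTIONS = frozenset({"zero", "nonzero", "unknown"})
_ARM_ASSIGNMENTS = frozenset({"equal_probability", "unequal_probability", "single_arm"})
_BALANCING = frozenset({"permuted_blocks", "other"})


@dataclass(frozen=True)
class RandomisationScheme:
    """A randomisation scheme operating within clusters/strata.

    Parameters
    ----------
    kind
        One of ``simple``, ``stratified_permuted_blocks``,
        ``cluster_randomised``, ``crossover_2x2``.
    block_size
        Block size ``n`` for stratified permuted blocks (``n >= 2``);
        must be omitted for every other kind.
    """

    kind: str
    block_size: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _SCHEME_KINDS:
            raise DesignError(f"unknown randomisation scheme kind {self.kind!r}")
        if self.kind == "stratified_permuted_blocks":
            if self.block_size is None or self.block_size < 2:
                raise DesignError("stratified_permuted_blocks requires block_size >= 2")
        elif self.block_size is not None:
            raise DesignError(f"block_size is only meaningful for permuted blocks, not {self.kind!r}")


def analytic_assignment_correlation(scheme: RandomisationScheme) -> float:
    """Closed-form within-cluster correlation of treatment assignments.

    Returns +1 for cluster randomisation (all patients in a cluster share an
    arm), −1 for a 2×2 crossover (the two observations on a patient are always
    in opposite arms), −1/(n−1) for stratified permuted blocks of size ``n``
    (forced balance makes assignments anti-correlated), and 0 for simple
    randomisation.
    """
    if scheme.kind == "cluster_randomised":
        return 1.0
    if scheme.kind == "crossover_2x2":
        return -1.0
    if scheme.kind == "stratified_permuted_blocks":
        return -1.0 / (scheme.block_size - 1)
    return 0.0


def empirical_assignment_correlation(
    assignments: Iterable[Tuple[object, int]] | pd.DataFrame,
) -> float:
    """Pairwise within-cluster correlation of arm indicators.

    The estimator pools all within-cluster pairs of distinct patients and
    computes the Pearson correlation of the two arm indicators over those
    pairs (each unordered pair contributes symmetrically, which is equivalent
    to using every ordered pair).  With cluster arm-totals ``s_j`` and sizes
    ``m_j`` this reduces to cluster-level sums, so the computation is O(J).

    Parameters
    ----------
    assignments
        Iterable of ``(cluster_id, arm)`` with arm coded 0/1, or a DataFrame
        with columns ``cluster_id`` and ``arm``.

    Raises
    ------
    DesignError
        If no cluster contains two patients ("no pairs") or all patients are
        in one arm ("degenerate arms").
    """
    if isinstance(assignments, pd.DataFrame):
        df = assignments[["cluster_id", "arm"]]
    else:
        df = pd.DataFrame(list(assignments), columns=["cluster_id", "arm"])
    arms = df["arm"].to_numpy()
    if not np.isin(arms, (0, 1)).all():
        raise DesignError("arm must be coded 0/1")
    grp = df.groupby("cluster_id")["arm"]
    s = grp.sum().to_numpy(dtype=float)  # arm-1 count per cluster
    m = grp.size().to_numpy(dtype=float)  # cluster size
    if arms.min() == arms.max():
        raise DesignError("degenerate arms: all patients in one arm")
    n_pairs = float(np.sum(m * (m - 1)))  # ordered pairs
    if n_pairs == 0:
        raise DesignError("no pairs: every cluster has a single patient")
    # Over ordered pairs (a, b): E[x_a x_b] via s_j^2 - s_j; marginal moments of
    # a pair member weight each patient by (m_j - 1).
    e_xy = float(np.sum(s * s - s)) / n_pairs
    mean = float(np.sum(s * (m - 1))) / n_pairs
    var = mean - mean * mean
    if var == 0.0:
        # Every patient appearing in a pair is in one arm: perfect concordance.
        return 1.0
    return (e_xy - mean * mean) / var


@dataclass(frozen=True)
class ClusteringSourceSpec:
    """Declarative description of one potential source of clustering.

    Parameters
    ----------
    name
        Label for the source (e.g. ``"surgeon"``).
    timing
        ``pre_randomisation`` (patients are in clusters before randomisation)
        or ``post_randomisation`` (patients are assigned to clusters after).
    icc_assumption
        ``zero``, ``nonzero`` or ``unknown``; ``unknown`` is treated as
        non-zero downstream — the conservative default, since assuming zero
        risks erroneously excluding non-ignorable clustering.
    used_in_randomisation
        Pre-randomisation only: was the cluster used in the randomisation
        process (stratification/balancing)?
    arm_assignment
        Post-randomisation only: ``equal_probability``,
        ``unequal_probability`` or ``single_arm``.
    balancing
        Pre-randomisation sources used in randomisation only: the balancing
        method, ``permuted_blocks`` (the default, and the usual meaning of
        stratified randomisation) or ``other`` (e.g. minimisation), for which
        the assignment-correlation sign is not determined.
    """

    name: str
    timing: str
    icc_assumption: str = "nonzero"
    used_in_randomisation: bool | None = None
    arm_assignment: str | None = None
    balancing: str = "permuted_blocks"

    def __post_init__(self) -> None:
        if self.timing not in _TIMINGS:
            raise DesignError(f"timing must be one of {sorted(_TIMINGS)}, got {self.timing!r}")
        if self.icc_assumption not in _ICC_ASSUMPTIONS:
            raise DesignError(f"icc_assumption must be one of {sorted(_ICC_ASSUMPTIONS)}")
        if self.balancing not in _BALANCING:
            raise DesignError(f"balancing must be one of {sorted(_BALANCING)}")
        if self.timing == "pre_randomisation":
            if self.used_in_randomisation is None:
                raise DesignError(f"{self.name!r}: pre-randomisation source needs used_in_randomisation")
            if self.arm_assignment is not None:
                raise DesignError(f"{self.name!r}: arm_assignment is meaningless for pre-randomisation clustering")
        else:
            if self.arm_assignment is None:
                raise DesignError(f"{self.name!r}: post-randomisation source needs arm_assignment")
            if self.arm_assignment not in _ARM_ASSIGNMENTS:
                raise DesignError(f"arm_assignment must be one of {sorted(_ARM_ASSIGNMENTS)}")
            if self.used_in_randomisation is not None:
                raise DesignError(f"{self.name!r}: used_in_randomisation is meaningless for post-randomisation clustering")


@dataclass(frozen=True)
class IgnorabilityVerdict:
    """Outcome of classifying a clustering source.

    ``status`` is ``ignorable`` iff the source cannot bias the treatment-effect
    standard error; then ``se_bias_direction`` is ``none`` and
    ``type1_consequence`` is ``valid``.  Otherwise the direction follows the
    sign of the within-cluster assignment correlation: positive → SE biased
    downward → inflated type I error; negative → SE biased upward →
    conservative; unknown sign → ``invalid`` (biased, direction undetermined).
    """

    status: str
    assignment_correlation_sign: str
    se_bias_direction: str
    type1_consequence: str
    rationale: str


def classify_source(spec: ClusteringSourceSpec) -> IgnorabilityVerdict:
    """Classify a clustering source as ignorable or non-ignorable.

    Decision rules: clustering is ignorable iff either correlation vanishes —
    the ICC is assumed zero; OR the clustering is pre-randomisation and the
    cluster was not used in the randomisation process; OR it is
    post-randomisation and both arms are assigned to clusters with equal
    probability.  Otherwise both correlations are non-zero and the source is
    non-ignorable, with the bias direction given by the assignment-correlation
    sign.
    """
    if spec.icc_assumption == "zero":
        return IgnorabilityVerdict(
            status="ignorable",
            assignment_correlation_sign="zero",
            se_bias_direction="none",
            type1_consequence="valid",
            rationale=f"{spec.name}: ICC assumed zero, so the clustering correction VE is zero.",
        )
    if spec.timing == "pre_randomisation":
        if not spec.used_in_randomisation:
            return IgnorabilityVerdict(
                status="ignorable",
                assignment_correlation_sign="zero",
                se_bias_direction="none",
                type1_consequence="valid",
                rationale=(
                    f"{spec.name}: pre-randomisation cluster not used in the randomisation "
                    "process, so treatment assignments are uncorrelated within clusters."
                ),
            )
        if spec.balancing == "permuted_blocks":
            return IgnorabilityVerdict(
                status="non_ignorable",
                assignment_correlation_sign="negative",
                se_bias_direction="upward",
                type1_consequence="conservative",
                rationale=(
                    f"{spec.name}: balanced on in the randomisation (permuted blocks within "
                    "cluster) — negative assignment correlation, SE biased upward."
                ),
            )
        return IgnorabilityVerdict(
            status="non_ignorable",
            assignment_correlation_sign="unknown",
            se_bias_direction="unknown",
            type1_consequence="invalid",
            rationale=(
                f"{spec.name}: used in the randomisation by a non-block balancing method; "
                "assignment correlation is non-zero but its sign is not determined."
            ),
        )
    # post-randomisation
    if spec.arm_assignment == "equal_probability":
        return IgnorabilityVerdict(
            status="ignorable",
            assignment_correlation_sign="zero",
            se_bias_direction="none",
            type1_consequence="valid",
            rationale=(
                f"{spec.name}: both arms assigned to clusters with equal probability, "
                "so treatment assignments are uncorrelated within clusters."
            ),
        )
    return IgnorabilityVerdict(
        status="non_ignorable",
        assignment_correlation_sign="positive",
        se_bias_direction="downward",
        type1_consequence="inflated",
        rationale=(
            f"{spec.name}: post-randomisation assignment to clusters with arm-dependent "
            f"probabilities ({spec.arm_assignment}) — positive assignment correlation, "
            "SE biased downward."
        ),
    )


@dataclass(frozen=True)
class VarianceDecomposition:
    """Var(beta_hat) = V0 + VE: no-clustering variance plus signed correction."""

    v0: float
    ve: float
    total: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if math.isnan(self.total):
            object.__setattr__(self, "total", self.v0 + self.ve)
        elif not math.isclose(self.total, self.v0 + self.ve, rel_tol=1e-9, abs_tol=1e-12):
            raise DesignError("total must equal v0 + ve")
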