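"""Patient-level trial simulation under a partially nested clustering model.

Outcomes follow the linear model

    y_ij = alpha + beta_treat * x_ij + u_j + e_ij

with independent e_ij ~ N(0, 1) and cluster (therapist) effects
u_j ~ N(0, sigma^2), where sigma^2 = rho / (1 - rho) yields intraclass
correlation rho given the unit error variance.  Patients are first randomised
1:1 and then assigned to one of J therapists by one of three post-randomisation
mechanisms:

``equal``
    every patient is assigned uniformly over all J therapists (assignment
    correlation 0 — ignorable clustering);
``partial_80_20``
    therapists are split into two equal sets; arm-1 patients go to the first
    set with probability 0.8 and to the second with 0.2, arm-0 patients with
    the reverse probabilities (positive assignment correlation);
``one_arm``
    each arm has its own dedicated half of the therapists and patients are
    assigned uniformly within it (assignment correlation 1).

A fourth, pre-randomisation design (``pre_blocks``) places patients in
clusters first and randomises within each cluster by permuted blocks,
inducing the negative assignment correlation −1/(block_size − 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Scenario",
    "SimulationError",
    "icc_to_cluster_variance",
    "randomise_arms",
    "assign_clusters_post",
    "generate_pre_randomised",
    "generate_outcomes",
    "simulate_trial",
    "validate_dataset",
]

POST_MECHANISMS = ("equal", "partial_80_20", "one_arm")
MECHANISMS = POST_MECHANISMS + ("pre_blocks",)

DATASET_COLUMNS = ["patient_id", "arm", "cluster_id", "outcome"]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Scenario:
    """One simulation cell.

    Parameters
    ----------
    n_clusters
        Number of therapists/clusters J.
    n_patients
        Number of patients N (even; allocation is forced 1:1).
    icc
        Intraclass correlation rho in [0, 1).
    mechanism
        ``equal``, ``partial_80_20``, ``one_arm`` or ``pre_blocks``.
    treatment_effect, intercept
        beta_treat and alpha of the outcome model.
    seed
        Base seed for this scenario's random streams.
    block_size
        Permuted-block size (even), required iff mechanism is ``pre_blocks``.
    """

    n_clusters: int
    n_patients: int
    icc: float
    mechanism: str
    treatment_effect: float = 0.0
    intercept: float = 0.0
    seed: int = 0
    block_size: int | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise SimulationError(f"mechanism must be one of {MECHANISMS}, got {self.mechanism!r}")
        if self.n_clusters < 2:
            raise SimulationError("need at least two clusters")
        if self.n_patients < 2 or self.n_patients % 2:
            raise SimulationError("n_patients must be a positive even integer")
        if not 0.0 <= self.icc < 1.0:
            raise SimulationError("icc must lie in [0, 1)")
        if self.mechanism in ("partial_80_20", "one_arm") and self.n_clusters % 2:
            raise SimulationError(f"{self.mechanism} requires an even number of clusters")
        if self.mechanism == "pre_blocks":
            if self.block_size is None or self.block_size < 2 or self.block_size % 2:
                raise SimulationError("pre_blocks requires an even block_size >= 2")
            per_cluster, rem = divmod(self.n_patients, self.n_clusters)
            if rem or per_cluster % self.block_size:
                raise SimulationError(
                    "pre_blocks requires n_patients divisible by n_clusters and "
                    "cluster size divisible by block_size"
                )
        elif self.block_size is not None:
            raise SimulationError("block_size is only meaningful for pre_blocks")

    @property
    def cluster_variance(self) -> float:
        return icc_to_cluster_variance(self.icc)


def icc_to_cluster_variance(rho: float) -> float:
    """Cluster-effect variance sigma^2 = rho/(1-rho) giving ICC rho with unit error variance."""
    if not 0.0 <= rho < 1.0:
        raise SimulationError("icc must lie in [0, 1)")
    return rho / (1.0 - rho)


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def randomise_arms(
    n_patients: int,
    allocation: str = "forced_equal",
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Randomise N patients 1:1 to arms 0/1.

    ``forced_equal`` returns a uniformly random permutation of N/2 zeros and
    N/2 ones; ``simple`` returns independent fair coin flips.
    """
    rng = _as_rng(seed)
    if n_patients < 2:
        raise SimulationError("need at least two patients")
    if allocation == "forced_equal":
        if n_patients % 2:
            raise SimulationError("forced_equal allocation requires even n_patients")
        arms = np.repeat(np.array([0, 1], dtype=np.int8), n_patients // 2)
        return rng.permutation(arms)
    if allocation == "simple":
        return (rng.random(n_patients) < 0.5).astype(np.int8)
    raise SimulationError(f"unknown allocation {allocation!r}")


def assign_clusters_post(
    arms: np.ndarray,
    n_clusters: int,
    mechanism: str,
    seed: int | np.random.Generator | None = None,
    caseload: str = "probabilistic",
) -> np.ndarray:
    """Assign already-randomised patients to clusters (therapists).

    ``caseload='probabilistic'`` (default) draws each patient's therapist
    independently per the mechanism's probabilities.  ``caseload='balanced'``
    instead deals out equal caseloads of N/J patients per therapist while
    honouring the mechanism's arm mixture in expectation (requires J | N).
    """
    rng = _as_rng(seed)
    arms = np.asarray(arms)
    n = arms.size
    if mechanism not in POST_MECHANISMS:
        raise SimulationError(f"mechanism must be one of {POST_MECHANISMS}")
    if mechanism in ("partial_80_20", "one_arm") and n_clusters % 2:
        raise SimulationError(f"{mechanism} requires an even number of clusters")
    half = n_clusters // 2
    if caseload == "probabilistic":
        if mechanism == "equal":
            return rng.integers(0, n_clusters, size=n, dtype=np.int64)
        within = rng.integers(0, half, size=n, dtype=np.int64)
        if mechanism == "one_arm":
            return within + arms * half
        p_first = np.where(arms == 1, 0.8, 0.2)
        in_first = rng.random(n) < p_first
        return within + np.where(in_first, 0, half)
    if caseload == "balanced":
        return _assign_balanced(arms, n_clusters, mechanism, rng)
    raise SimulationError(f"unknown caseload mode {caseload!r}")


def _assign_balanced(arms: np.ndarray, n_clusters: int, mechanism: str, rng: np.random.Generator) -> np.ndarray:
    n = arms.size
    if n % n_clusters:
        raise SimulationError("balanced caseload requires n_patients divisible by n_clusters")
    per = n // n_clusters
    out = np.empty(n, dtype=np.int64)
    if mechanism == "equal":
        slots = rng.permutation(np.repeat(np.arange(n_clusters), per))
        out[:] = slots
        return out
    half = n_clusters // 2
    for arm in (0, 1):
        idx = np.flatnonzero(arms == arm)
        if mechanism == "one_arm":
            # each arm's N/2 patients fill its J/2 therapists' caseloads of N/J
            pool = np.repeat(np.arange(half) + arm * half, per)
        else:  # partial_80_20: 80% of each arm to its favoured set, spread evenly
            fav = np.arange(half) if arm == 1 else np.arange(half) + half
            oth = np.arange(half) + half if arm == 1 else np.arange(half)
            n_fav = int(round(0.8 * idx.size))
            pool = np.concatenate(
                [np.resize(rng.permutation(fav), n_fav), np.resize(rng.permutation(oth), idx.size - n_fav)]
            )
        out[idx] = rng.permutation(pool[: idx.size])
    return out


def generate_pre_randomised(
    n_clusters: int,
    patients_per_cluster: int,
    block_size: int,
    seed: int | np.random.Generator | None = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Pre-randomisation clustering with stratified permuted blocks.

    Patients arrive pre-grouped into ``n_clusters`` clusters of
    ``patients_per_cluster`` each and are randomised within cluster in
    permuted blocks of ``block_size`` (each block a random permutation of
    equal numbers of 0s and 1s).  Returns ``(arms, cluster_ids)``.
    """
    rng = _as_rng(seed)
    if block_size < 2 or block_size % 2:
        raise SimulationError("block_size must be even and >= 2")
    if patients_per_cluster % block_size:
        raise SimulationError("patients_per_cluster must be divisible by block_size")
    n = n_clusters * patients_per_cluster
    cluster_ids = np.repeat(np.arange(n_clusters), patients_per_cluster)
    n_blocks = n // block_size
    pattern = np.tile(
        np.repeat(np.array([0, 1], dtype=np.int8), block_size // 2), (n_blocks, 1)
    )
    # independent permutation within each block
    order = rng.random((n_blocks, block_size)).argsort(axis=1)
    arms = np.take_along_axis(pattern, order, axis=1).reshape(-1)
    return arms, cluster_ids


def generate_outcomes(
    arms: np.ndarray,
    cluster_ids: np.ndarray,
    intercept: float = 0.0,
    treatment_effect: float = 0.0,
    cluster_variance: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw outcomes y = alpha + beta*x + u_cluster + e and assemble a dataset.

    One cluster effect u_j ~ N(0, cluster_variance) is drawn per distinct
    cluster id; errors are standard normal.
    """
    rng = _as_rng(seed)
    arms = np.asarray(arms)
    cluster_ids = np.asarray(cluster_ids)
    if arms.shape != cluster_ids.shape:
        raise SimulationError("arms and cluster_ids must have the same length")
    if cluster_variance < 0:
        raise SimulationError("cluster_variance must be nonnegative")
    uniq, inverse = np.unique(cluster_ids, return_inverse=True)
    u = rng.normal(0.0, np.sqrt(cluster_variance), size=uniq.size)
    e = rng.normal(size=arms.size)
    y = intercept + treatment_effect * arms + u[inverse] + e
    return pd.DataFrame(
        {
            "patient_id": np.arange(1, arms.size + 1),
            "arm": arms.astype(np.int8),
            "cluster_id": cluster_ids,
            "outcome": y,
        }
    )


def simulate_trial(scenario: Scenario, caseload: str = "probabilistic") -> pd.DataFrame:
    """Simulate one complete trial dataset for a scenario."""
    rng = np.random.default_rng(scenario.seed)
    if scenario.mechanism == "pre_blocks":
        arms, clusters = generate_pre_randomised(
            scenario.n_clusters,
            scenario.n_patients // scenario.n_clusters,
            scenario.block_size,
            rng,
        )
    else:
        arms = randomise_arms(scenario.n_patients, "forced_equal", rng)
        clusters = assign_clusters_post(arms, scenario.n_clusters, scenario.mechanism, rng, caseload)
    return generate_outcomes(
        arms,
        clusters,
        scenario.intercept,
        scenario.treatment_effect,
        scenario.cluster_variance,
        rng,
    )


def validate_dataset(df: pd.DataFrame) -> pd.DataFrame:
    """Check the patient-level dataset contract and return the frame.

    Requires columns patient_id, arm (0/1, both present), cluster_id, outcome,
    with unique patient ids.
    """
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise SimulationError(f"dataset missing columns {missing}")
    if df["patient_id"].duplicated().any():
        raise SimulationError("duplicate patient_id")
    arms = df["arm"].to_numpy()
    if not np.isin(arms, (0, 1)).all():
        raise SimulationError("arm must be coded 0/1")
    if arms.min() == arms.max():
        raise SimulationError("both arms must be present")
    return df
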