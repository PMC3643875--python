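"""Vectorised Monte-Carlo engine for the simulation study.

Simulates whole batches of replicate trials as (reps, N) arrays and computes
each analysis's t-test in closed form across the batch:

* unadjusted — difference in arm means with the pooled-variance two-sample t;
* fixed effects — within-cluster demeaning of outcome and treatment followed
  by simple regression of the demeaned variables (algebraically identical to
  OLS with cluster indicator variables), df = N − J_occupied − 1;
* cluster summaries — two-sample t on the occupied clusters' mean outcomes,
  df = J_occupied − 2.

Per-dataset equivalence with the reference estimators in
:mod:`clustrial.estimators` is asserted in the test suite.

Random streams are Philox generators keyed by (master seed, scenario key,
batch index), so each scenario/batch is reproducible in isolation and the
whole study is a pure function of the master seed.
"""

from __future__ import annotations

import zlib
from typing import Dict, Iterable, List, Tuple

import numpy as np
from scipy import stats

from .simulate import Scenario

BATCH_SIZE = 1000


def scenario_key(sc: Scenario) -> int:
    """Stable 32-bit key derived from a scenario's defining fields."""
    desc = (
        f"{sc.n_clusters}|{sc.n_patients}|{sc.icc:.10g}|{sc.mechanism}|"
        f"{sc.treatment_effect:.10g}|{sc.intercept:.10g}|{sc.block_size}"
    )
    return zlib.crc32(desc.encode())


def _rng(master_seed: int, sc: Scenario, batch: int) -> np.random.Generator:
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, scenario_key(sc), batch])
    return np.random.Generator(np.random.Philox(ss))


def simulate_batch(
    sc: Scenario, rng: np.random.Generator, reps: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate `reps` replicate trials; returns (arms, clusters, y), each (reps, N)."""
    n, j = sc.n_patients, sc.n_clusters
    half_j = j // 2
    if sc.mechanism == "pre_blocks":
        per_cluster = n // j
        clusters = np.broadcast_to(np.repeat(np.arange(j), per_cluster), (reps, n)).copy()
        bs = sc.block_size
        n_blocks = n // bs
        pattern = np.broadcast_to(
            np.repeat(np.array([0, 1], dtype=np.int8), bs // 2), (reps, n_blocks, bs)
        )
        order = rng.random((reps, n_blocks, bs)).argsort(axis=2)
        arms = np.take_along_axis(pattern, order, axis=2).reshape(reps, n)
    else:
        # forced 1:1 allocation: random permutation of N/2 zeros and ones
        ranks = rng.random((reps, n)).argsort(axis=1).argsort(axis=1)
        arms = (ranks >= n // 2).astype(np.int8)
        if sc.mechanism == "equal":
            clusters = rng.integers(0, j, size=(reps, n))
        elif sc.mechanism == "one_arm":
            clusters = rng.integers(0, half_j, size=(reps, n)) + arms * half_j
        else:  # partial_80_20
            within = rng.integers(0, half_j, size=(reps, n))
            p_first = np.where(arms == 1, 0.8, 0.2)
            in_first = rng.random((reps, n)) < p_first
            clusters = within + np.where(in_first, 0, half_j)
    u = rng.normal(0.0, np.sqrt(sc.cluster_variance), size=(reps, j))
    e = rng.standard_normal((reps, n))
    y = sc.intercept + sc.treatment_effect * arms + np.take_along_axis(u, clusters, axis=1) + e
    return arms, clusters, y


def _pvals(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def unadjusted_stats(arms: np.ndarray, y: np.ndarray) -> Dict[str, np.ndarray]:
    """Pooled two-sample t across a batch: beta, se, df, p, failed."""
    reps, n = y.shape
    x = arms.astype(float)
    n1 = x.sum(axis=1)
    n0 = n - n1
    m1 = (y * x).sum(axis=1) / n1
    m0 = (y * (1.0 - x)).sum(axis=1) / n0
    beta = m1 - m0
    fitted = m0[:, None] + beta[:, None] * x
    s2 = ((y - fitted) ** 2).sum(axis=1) / (n - 2)
    se = np.sqrt(s2 * (1.0 / n0 + 1.0 / n1))
    df = np.full(reps, n - 2, dtype=float)
    failed = ~(se > 0)
    t = np.divide(beta, se, out=np.zeros_like(beta), where=~failed)
    p = _pvals(t, df)
    p[failed] = np.nan
    return {"beta": beta, "se": se, "df": df, "p": p, "failed": failed}


def _cluster_sums(clusters: np.ndarray, values: np.ndarray, j: int) -> np.ndarray:
    """Per-replicate per-cluster sums via a flat bincount; values may be None for counts."""
    reps, n = clusters.shape
    flat = clusters + j * np.arange(reps)[:, None]
    if values is None:
        return np.bincount(flat.ravel(), minlength=reps * j).reshape(reps, j).astype(float)
    return np.bincount(flat.ravel(), weights=values.ravel(), minlength=reps * j).reshape(reps, j)


def fixed_effects_stats(arms: np.ndarray, clusters: np.ndarray, y: np.ndarray, j: int) -> Dict[str, np.ndarray]:
    """Cluster-indicator OLS via within-cluster demeaning across a batch."""
    reps, n = y.shape
    x = arms.astype(float)
    counts = _cluster_sums(clusters, None, j)
    occupied = counts > 0
    safe = np.where(occupied, counts, 1.0)
    mean_y = _cluster_sums(clusters, y, j) / safe
    mean_x = _cluster_sums(clusters, x, j) / safe
    yd = y - np.take_along_axis(mean_y, clusters, axis=1)
    xd = x - np.take_along_axis(mean_x, clusters, axis=1)
    sxx = (xd * xd).sum(axis=1)
    sxy = (xd * yd).sum(axis=1)
    j_occ = occupied.sum(axis=1)
    df = (n - j_occ - 1).astype(float)
    failed = (sxx <= 1e-12) | (df < 1)
    sxx_safe = np.where(failed, 1.0, sxx)
    beta = sxy / sxx_safe
    resid = yd - beta[:, None] * xd
    s2 = (resid**2).sum(axis=1) / np.where(df < 1, 1.0, df)
    se = np.sqrt(s2 / sxx_safe)
    failed |= ~(se > 0)
    t = np.divide(beta, se, out=np.zeros_like(beta), where=~failed)
    p = _pvals(t, df)
    p[failed] = np.nan
    return {"beta": beta, "se": se, "df": df, "p": p, "failed": failed}


def cluster_summary_stats(clusters: np.ndarray, y: np.ndarray, j: int) -> Dict[str, np.ndarray]:
    """Two-sample t on cluster means for the one_arm design across a batch.

    Clusters 0..J/2−1 serve arm 0 and J/2..J−1 serve arm 1 by construction;
    unoccupied clusters contribute no mean and degrees of freedom shrink
    accordingly.
    """
    reps, n = y.shape
    half = j // 2
    counts = _cluster_sums(clusters, None, j)
    occupied = counts > 0
    sums = _cluster_sums(clusters, y, j)
    means = np.where(occupied, sums / np.where(occupied, counts, 1.0), np.nan)
    m_lo, m_hi = means[:, :half], means[:, half:]
    k0 = occupied[:, :half].sum(axis=1).astype(float)
    k1 = occupied[:, half:].sum(axis=1).astype(float)
    failed = (k0 < 2) | (k1 < 2)
    with np.errstate(invalid="ignore"):
        mean0 = np.nanmean(m_lo, axis=1)
        mean1 = np.nanmean(m_hi, axis=1)
        var0 = np.nansum((m_lo - mean0[:, None]) ** 2, axis=1) / np.maximum(k0 - 1, 1.0)
        var1 = np.nansum((m_hi - mean1[:, None]) ** 2, axis=1) / np.maximum(k1 - 1, 1.0)
    df = np.maximum(k0 + k1 - 2, 1.0)
    s2 = ((k0 - 1) * var0 + (k1 - 1) * var1) / df
    se = np.sqrt(s2 * (1.0 / np.maximum(k0, 1.0) + 1.0 / np.maximum(k1, 1.0)))
    beta = mean1 - mean0
    failed |= ~(se > 0)
    t = np.divide(beta, se, out=np.zeros_like(beta), where=~failed)
    p = _pvals(t, df)
    p[failed] = np.nan
    return {"beta": beta, "se": se, "df": df, "p": p, "failed": failed}


def batch_stats(
    sc: Scenario, arms: np.ndarray, clusters: np.ndarray, y: np.ndarray, methods: Iterable[str]
) -> Dict[str, Dict[str, np.ndarray]]:
    out: Dict[str, Dict[str, np.ndarray]] = {}
    for m in methods:
        if m == "unadjusted":
            out[m] = unadjusted_stats(arms, y)
        elif m == "fixed_effects":
            out[m] = fixed_effects_stats(arms, clusters, y, sc.n_clusters)
        elif m == "cluster_summaries":
            out[m] = cluster_summary_stats(clusters, y, sc.n_clusters)
        else:
            raise ValueError(f"unknown method {m!r}")
    return out


def run_replicates(
    sc: Scenario,
    methods: List[str],
    reps: int,
    master_seed: int,
    batch_size: int = BATCH_SIZE,
) -> Dict[str, Dict[str, np.ndarray]]:
    """Run `reps` replicate trials and return per-method stacked statistics."""
    chunks: Dict[str, List[Dict[str, np.ndarray]]] = {m: [] for m in methods}
    done = 0
    batch_idx = 0
    while done < reps:
        r = min(batch_size, reps - done)
        rng = _rng(master_seed, sc, batch_idx)
        arms, clusters, y = simulate_batch(sc, rng, r)
        for m, st in batch_stats(sc, arms, clusters, y, methods).items():
            chunks[m].append(st)
        done += r
        batch_idx += 1
    return {
        m: {k: np.concatenate([c[k] for c in lst]) for k in lst[0]}
        for m, lst in chunks.items()
    }
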