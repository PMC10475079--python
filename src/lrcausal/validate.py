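"""In-silico validation statistics for called LR pairs.

Two families of checks:

* Gene-set enrichment — the enrichment ratio of an annotation set A in a
  query set B is |A ∩ B| / |B|, with hypergeometric upper-tail
  (over-enrichment) and lower-tail (depletion) p-values against a stated
  gene universe.

* Transcription-inhibition deltas — with per-condition interaction scores
  for early 2-cell, late 2-cell and transcription-inhibited embryos, the
  effect of blocking zygotic genome activation on a pair is

      delta = |log10(IS_inhibited + 1) - log10(IS_late2c + 1)|

  (the early 2-cell baseline cancels algebraically).  Affected pairs are
  found by two rounds of hierarchical clustering (complete linkage,
  Euclidean): round one keeps the higher-variance half of the pairs, round
  two returns the half with the larger mean delta.  A one-sided Welch t-test
  compares delta distributions between called and uncalled pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats

from .datatypes import GeneSet, LRPair

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "DeltaResult",
    "enrichment_ratio",
    "delta_analysis",
    "find_affected_pairs",
    "compare_delta_groups",
]

CONDITIONS = ("early_2cell", "late_2cell", "inhibited")


@dataclass
class EnrichmentResult:
    set_a: str
    set_b: str
    ratio: float
    overlap: int
    p_upper: float       # over-enrichment
    p_lower: float       # depletion
    universe_size: int


@dataclass
class DeltaResult:
    pair: LRPair
    is_early2c: float
    is_late2c: float
    is_inhibited: float
    delta: float
    affected: bool = False


def enrichment_ratio(a: GeneSet, b: GeneSet, universe: GeneSet) -> EnrichmentResult:
    """Enrichment ratio |A ∩ B| / |B| with hypergeometric tail p-values.

    Members of B outside the universe are dropped with a warning; A is
    restricted to the universe.  ``p_upper`` tests whether the observed
    overlap is higher than expected, ``p_lower`` whether it is lower.
    """
    if not b.members:
        raise ValueError("query set B is empty")
    b_in = b.members & universe.members
    dropped = len(b.members) - len(b_in)
    if dropped:
        logger.warning("enrichment: dropped %d genes of %s outside the universe", dropped, b.name)
    if not b_in:
        raise ValueError("query set B is empty after restricting to universe")
    a_in = a.members & universe.members
    overlap = len(a_in & b_in)
    M, K, N = len(universe.members), len(a_in), len(b_in)
    p_upper = float(scipy.stats.hypergeom.sf(overlap - 1, M, K, N))   # P(X >= overlap)
    p_lower = float(scipy.stats.hypergeom.cdf(overlap, M, K, N))      # P(X <= overlap)
    return EnrichmentResult(
        set_a=a.name,
        set_b=b.name,
        ratio=overlap / N,
        overlap=overlap,
        p_upper=min(1.0, p_upper),
        p_lower=min(1.0, p_lower),
        universe_size=M,
    )


def delta_analysis(is_table: pd.DataFrame) -> list[DeltaResult]:
    """Per-pair inhibition delta from a (pair x condition) interaction-score table.

    ``is_table`` must be indexed by pair (LRPair or "L-R" strings) with the
    columns ``early_2cell``, ``late_2cell``, ``inhibited``; interaction
    scores are per-condition pseudo-bulk values and must be >= 0.
    """
    missing = [c for c in CONDITIONS if c not in is_table.columns]
    if missing:
        raise ValueError(f"missing condition column(s): {missing}")
    if np.any(is_table[list(CONDITIONS)].to_numpy() < 0):
        raise ValueError("interaction scores must be non-negative")
    out = []
    for key, row in is_table.iterrows():
        pair = key if isinstance(key, LRPair) else LRPair(*str(key).split("-", 1))
        delta = abs(np.log10(row["inhibited"] + 1.0) - np.log10(row["late_2cell"] + 1.0))
        out.append(
            DeltaResult(
                pair=pair,
                is_early2c=float(row["early_2cell"]),
                is_late2c=float(row["late_2cell"]),
                is_inhibited=float(row["inhibited"]),
                delta=float(delta),
            )
        )
    return out


def _cut2(profiles: np.ndarray) -> np.ndarray:
    Z = scipy.cluster.hierarchy.linkage(profiles, method="complete", metric="euclidean")
    return scipy.cluster.hierarchy.fcluster(Z, t=2, criterion="maxclust")


def find_affected_pairs(is_table: pd.DataFrame) -> set:
    """Two-round hierarchical clustering to find inhibition-affected pairs.

    Round 1 clusters pairs on their condition profiles (complete linkage,
    Euclidean, cut at 2) and keeps the higher-variance cluster ("variable"
    pairs); round 2 reclusters those and returns the cluster with the larger
    mean delta ("affected").  Clustering runs on the raw score profiles, so
    baseline magnitude participates in round 1 and the delta rule does the
    discriminating in round 2; see the methods note for the implications.
    Returns a set of index keys of ``is_table``.
    """
    if len(is_table) < 4:
        raise ValueError("need >= 4 pairs for two-round clustering")
    raw = is_table[list(CONDITIONS)].to_numpy(dtype=float)
    profiles = raw
    if np.allclose(profiles.var(axis=0), 0):
        logger.warning("all pair profiles identical; no affected pairs")
        return set()
    labels1 = _cut2(profiles)
    var_by_cluster = {c: profiles[labels1 == c].var() for c in (1, 2)}
    keep = max(var_by_cluster, key=lambda c: var_by_cluster[c])
    kept_idx = np.nonzero(labels1 == keep)[0]
    if len(kept_idx) < 2:
        logger.warning("fewer than 2 pairs survive round-1 clustering")
        return set()
    deltas = np.abs(
        np.log10(raw[:, 2] + 1.0) - np.log10(raw[:, 1] + 1.0)
    )
    labels2 = _cut2(profiles[kept_idx])
    mean_delta = {c: deltas[kept_idx[labels2 == c]].mean() for c in np.unique(labels2)}
    affected_cluster = max(mean_delta, key=lambda c: mean_delta[c])
    affected = kept_idx[labels2 == affected_cluster]
    return set(is_table.index[affected])


def compare_delta_groups(
    elr_deltas: np.ndarray, non_elr_deltas: np.ndarray
) -> tuple[float, float]:
    """One-sided Welch t-test that called-pair deltas are lower than uncalled.

    Returns ``(t, p)`` for H1: mean(elr_deltas) < mean(non_elr_deltas).
    Identical constant groups give p = 0.5 by the symmetric-null convention.
    """
    a = np.asarray(elr_deltas, dtype=float)
    b = np.asarray(non_elr_deltas, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    if np.std(a) < 1e-300 and np.std(b) < 1e-300:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 0.5
        return (-np.inf, 0.0) if a.mean() < b.mean() else (np.inf, 1.0)
    res = scipy.stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return float(res.statistic), float(res.pvalue)
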