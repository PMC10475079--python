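"""TF-centered co-expression regulons, temporal-TF calls, and tTF clustering.

The reference analysis built regulons with a mutual-information network and
ran master-regulator analysis against trajectory-variable genes.  Here the
network is a permutation-calibrated Spearman co-expression net (same
interface, same downstream contract: a list of temporal TFs with activity
series); regulons can also be imported from a TSV produced by external
network software.

A TF is called *temporal* (tTF) when its regulon is enriched, by an upper-tail
hypergeometric test with Benjamini-Hochberg adjustment, for genes that vary
along the trajectory.  tTFs are then grouped by Ward hierarchical clustering
of their z-scored expression profiles over ordered cells, and each cluster's
activity series (mean member profile) is the unit the Granger stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, GeneSet, OrderedSeries

logger = logging.getLogger(__name__)

__all__ = [
    "Regulon",
    "TTFClusters",
    "build_regulons",
    "read_regulons",
    "write_regulons",
    "variable_genes",
    "call_temporal_tfs",
    "cluster_ttfs",
]


@dataclass
class Regulon:
    """One TF and its putative co-expression targets."""

    tf: str
    targets: set[str]
    target_stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    # target_stats columns: target, stat (Spearman rho), pval (permutation)

    def __post_init__(self) -> None:
        if self.tf in self.targets:
            raise ValueError(f"regulon of {self.tf} contains itself")


@dataclass
class TTFClusters:
    """tTF cluster assignments plus per-cluster activity series."""

    assignments: dict[str, int]            # tf -> cluster id in 1..k
    k: int
    activity: dict[int, OrderedSeries]     # cluster id -> mean member profile

    def cluster_members(self, cid: int) -> list[str]:
        return sorted(tf for tf, c in self.assignments.items() if c == cid)


def _rank_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit norm (for fast Spearman)."""
    ranks = scipy.stats.rankdata(X, axis=1)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranks, axis=1, keepdims=True)
    norms[norms < 1e-12] = 1.0
    return ranks / norms


def build_regulons(
    mat: ExpressionMatrix,
    tf_list: list[str],
    n_perm: int = 100,
    alpha_net: float = 0.01,
    rng: np.random.Generator | int | None = 0,
) -> list[Regulon]:
    """Per-TF Spearman co-expression regulons with a permutation-calibrated cutoff.

    For each TF the null distribution of |rho| is built by correlating
    ``n_perm`` cell-permuted copies of the TF profile against all genes;
    targets are genes whose observed |rho| exceeds the (1 - alpha_net)
    quantile of that null.  Empirical p-values are stored per target.
    """
    if mat.n_cells < 20:
        raise ValueError("need >= 20 cells to build regulons")
    rng = np.random.default_rng(rng)
    present = [tf for tf in tf_list if tf in mat]
    absent = [tf for tf in tf_list if tf not in mat]
    if absent:
        logger.warning("build_regulons: %d TFs absent from matrix (e.g. %s)", len(absent), absent[:3])
    if not present:
        raise ValueError("no TF from tf_list found in the matrix")

    R = _rank_rows(mat.values)                     # genes x cells, unit-norm centered ranks
    gene_index = {g: i for i, g in enumerate(mat.gene_ids)}
    regulons: list[Regulon] = []
    n_cells = mat.n_cells
    for tf in present:
        ti = gene_index[tf]
        obs = R @ R[ti]                            # Spearman rho vs all genes
        # permutation null: correlate permuted TF ranks against all genes
        perm_rhos = np.empty((n_perm, mat.n_genes))
        for p in range(n_perm):
            perm = R[ti][rng.permutation(n_cells)]
            perm_rhos[p] = R @ perm
        null_abs = np.abs(perm_rhos).ravel()
        thresh = float(np.quantile(null_abs, 1.0 - alpha_net))
        mask = np.abs(obs) > thresh
        mask[ti] = False
        targets = [mat.gene_ids[i] for i in np.nonzero(mask)[0]]
        # empirical p per target against the pooled null
        sorted_null = np.sort(null_abs)
        n_ge = len(sorted_null) - np.searchsorted(sorted_null, np.abs(obs[mask]), side="left")
        pvals = (1.0 + n_ge) / (len(sorted_null) + 1.0)
        stats = pd.DataFrame({"target": targets, "stat": obs[mask], "pval": pvals})
        regulons.append(Regulon(tf=tf, targets=set(targets), target_stats=stats))
    return regulons


def write_regulons(regulons: list[Regulon], path) -> None:
    rows = []
    for r in regulons:
        if len(r.target_stats):
            for _, row in r.target_stats.iterrows():
                rows.append((r.tf, row["target"], row["stat"], row["pval"]))
        else:
            for t in sorted(r.targets):
                rows.append((r.tf, t, np.nan, np.nan))
    pd.DataFrame(rows, columns=["tf", "target", "stat", "pval"]).to_csv(path, sep="\t", index=False)


def read_regulons(path) -> list[Regulon]:
    """Import regulons from a (tf, target, stat, pval) TSV, e.g. external network output."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    out = []
    for tf, grp in df.groupby("tf", sort=False):
        grp = grp[grp["target"] != tf]
        out.append(
            Regulon(tf=str(tf), targets=set(grp["target"]), target_stats=grp.reset_index(drop=True))
        )
    return out


def variable_genes(
    mat: ExpressionMatrix,
    ordering: list[str],
    n_top: int = 2000,
    winsz: float = 0.1,
) -> GeneSet:
    """Top-N genes by variance of the kernel-smoothed profile along the ordering.

    Smoothing (Gaussian kernel, bandwidth ``winsz`` on rank positions rescaled
    to [0, 1]) suppresses cell-level noise so the ranking reflects genuine
    pseudotime dependence rather than dispersion.
    """
    sub = mat.subset_cells(ordering)
    n = sub.n_cells
    t = np.linspace(0.0, 1.0, n)
    w = np.exp(-((t[:, None] - t[None, :]) ** 2) / (2.0 * winsz**2))
    w = w / w.sum(axis=1, keepdims=True)
    smooth = sub.values @ w.T
    var = smooth.var(axis=1)
    top = np.argsort(var)[::-1][: min(n_top, sub.n_genes)]
    return GeneSet("variable_genes", [sub.gene_ids[i] for i in top])


def call_temporal_tfs(
    regulons: list[Regulon],
    variable: GeneSet,
    universe: GeneSet,
    alpha_mra: float = 0.01,
) -> list[str]:
    """Master-regulator analysis: TFs whose regulons are enriched for variable genes.

    Upper-tail hypergeometric test of the regulon/variable-gene overlap inside
    the given universe, BH-adjusted across TFs; returns TFs with adjusted
    p < alpha_mra in input order.
    """
    var_set = variable.members & universe.members
    if not var_set:
        raise ValueError("variable gene set is empty (after restricting to universe)")
    M = len(universe.members)
    n_var = len(var_set)
    tfs, pvals = [], []
    for r in regulons:
        targets = r.targets & universe.members
        if not targets:
            tfs.append(r.tf)
            pvals.append(1.0)
            continue
        k = len(targets & var_set)
        # P(X >= k) with X ~ Hypergeom(M, n_var, |targets|)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, n_var, len(targets)))
        tfs.append(r.tf)
        pvals.append(min(1.0, p))
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [tf for tf, q in zip(tfs, adj) if q < alpha_mra]


def cluster_ttfs(
    mat: ExpressionMatrix,
    ttfs: list[str],
    ordering: list[str],
    k: int = 6,
    zscore: bool = True,
) -> TTFClusters:
    """Ward hierarchical clustering of tTF expression profiles, cut at k.

    Profiles are z-scored per TF (so shape, not amplitude, drives the Ward
    distances) unless ``zscore=False``.  Clusters are renumbered by ascending
    position of their activity peak along the ordering, so cluster 1 is the
    earliest program; labels are then invariant to input TF order.  Activity
    is the mean member profile per cluster.
    """
    ttfs = [tf for tf in ttfs if tf in mat]
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(ttfs) < k:
        raise ValueError(f"k={k} exceeds number of tTFs present ({len(ttfs)})")
    profiles = np.vstack([mat.gene_over(tf, ordering) for tf in ttfs])
    if zscore:
        mu = profiles.mean(axis=1, keepdims=True)
        sd = profiles.std(axis=1, keepdims=True)
        sd[sd < 1e-12] = 1.0
        profiles = (profiles - mu) / sd
    if k == 1:
        raw = np.ones(len(ttfs), dtype=int)
    else:
        # sort TFs so linkage input order (and thus tie resolution) is canonical
        order = sorted(range(len(ttfs)), key=lambda i: ttfs[i])
        Z = scipy.cluster.hierarchy.linkage(profiles[order], method="ward")
        labels_sorted = scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust")
        raw = np.empty(len(ttfs), dtype=int)
        for pos, i in enumerate(order):
            raw[i] = labels_sorted[pos]
    positions = np.arange(len(ordering), dtype=float)
    peak_pos = {}
    activities = {}
    for cid in sorted(set(raw)):
        members = raw == cid
        act = profiles[members].mean(axis=0)
        activities[cid] = act
        peak_pos[cid] = int(np.argmax(act))
    renum = {old: new + 1 for new, old in enumerate(sorted(activities, key=lambda c: (peak_pos[c], c)))}
    assignments = {tf: renum[c] for tf, c in zip(ttfs, raw)}
    activity = {
        renum[c]: OrderedSeries(positions, activities[c], label=f"C{renum[c]}") for c in activities
    }
    return TTFClusters(assignments=assignments, k=len(activity), activity=activity)
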