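"""Cell ordering and kernel interpolation onto a uniform pseudotime grid.

Every time-series computation in the package consumes either a per-cell
ordering (autocrine analysis on one lineage) or interpolated signals on a
common uniform grid (paracrine analysis across two lineages of unequal cell
number).  Interpolation uses a Gaussian kernel of bandwidth ``winsz`` on
pseudotime rescaled to [0, 1]: the value at grid point ``t`` is the
kernel-weighted mean of the observed values, a convex combination, so the
output range never exceeds the input range.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CellMetadata, ExpressionMatrix, InterpolationParams, OrderedSeries

__all__ = [
    "order_cells",
    "fallback_pseudotime",
    "interpolate",
    "interaction_series_paracrine",
    "cell_series",
    "break_ties",
]

_TIE_EPS = 1e-9


def order_cells(meta: CellMetadata, stage_order: list[str] | None = None) -> list[str]:
    """Order cells lexicographically by (stage index, pseudotime, cell id).

    Cells lacking pseudotime sort after timed cells within their stage, by
    cell id, so the ordering is deterministic across runs.
    """
    stages = stage_order if stage_order is not None else meta.stage_order
    stage_rank = {s: i for i, s in enumerate(stages)}
    unknown = set(meta.table["stage"].astype(str)) - set(stage_rank)
    if unknown:
        raise ValueError(f"stage(s) absent from stage_order: {sorted(unknown)}")
    pt = meta.table["pseudotime"].astype(float)
    keys = sorted(
        meta.table.index,
        key=lambda c: (
            stage_rank[str(meta.table.at[c, "stage"])],
            0 if np.isfinite(pt[c]) else 1,          # timed cells first
            pt[c] if np.isfinite(pt[c]) else 0.0,
            str(c),
        ),
    )
    return [str(c) for c in keys]


def fallback_pseudotime(
    mat: ExpressionMatrix,
    meta: CellMetadata,
    n_top_genes: int = 2000,
) -> CellMetadata:
    """Assign pseudotime by projection onto PC1 of the top-variable genes.

    A simple stand-in for a full trajectory method: the first principal
    component of the cells, sign-oriented so stage-mean pseudotime is
    nondecreasing along the declared stage order, shifted to be >= 0.
    """
    if len(meta.stage_order) < 2:
        raise ValueError("fallback pseudotime requires >= 2 stages")
    meta.check_against(mat)
    sub = mat.subset_cells(meta.cell_ids)
    X = sub.values
    var = X.var(axis=1)
    if np.all(var < 1e-15):
        raise ValueError("expression matrix is constant; cannot derive pseudotime")
    top = np.argsort(var)[::-1][: min(n_top_genes, X.shape[0])]
    Xc = X[top] - X[top].mean(axis=1, keepdims=True)
    # PC1 score per cell via SVD of genes x cells centered block
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    score = Vt[0]
    # orient so stage means are nondecreasing along stage_order
    stage_idx = np.array([meta.stage_order.index(str(s)) for s in meta.table["stage"]])
    means = np.array([score[stage_idx == i].mean() for i in np.unique(stage_idx)])
    if len(means) > 1 and np.polyfit(np.arange(len(means)), means, 1)[0] < 0:
        score = -score
    score = score - score.min()
    return meta.with_pseudotime(pd.Series(score, index=meta.cell_ids))


def break_ties(positions: np.ndarray) -> np.ndarray:
    """Make positions strictly increasing by perturbing ties with +k*eps."""
    pos = np.asarray(positions, dtype=float).copy()
    if len(pos) >= 2 and not np.all(np.diff(pos) > 0):
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be nondecreasing before tie-breaking")
        for i in range(1, len(pos)):
            if pos[i] <= pos[i - 1]:
                pos[i] = pos[i - 1] + _TIE_EPS
    return pos


def cell_series(
    mat: ExpressionMatrix,
    ordering: list[str],
    gene: str,
    positions: np.ndarray | None = None,
) -> OrderedSeries:
    """Expression of one gene along an ordering as an :class:`OrderedSeries`.

    The autocrine workflow indexes by rank (0..n-1), which Granger regression
    is invariant to given a fixed order; raw pseudotime positions may be
    supplied for interpolation.
    """
    values = mat.gene_over(gene, ordering)
    if positions is None:
        positions = np.arange(len(ordering), dtype=float)
    else:
        positions = break_ties(np.asarray(positions, dtype=float))
    return OrderedSeries(positions, values, label=gene)


def interpolate(series: OrderedSeries, params: InterpolationParams | None = None) -> OrderedSeries:
    """Gaussian-kernel interpolation onto ``num_pts`` uniform points of [0, 1].

    Positions are rescaled to [0, 1]; the value at grid point ``t`` is
    ``sum_i w_i v_i / sum_i w_i`` with ``w_i = exp(-(t - t_i)^2 / (2 winsz^2))``.
    """
    params = params or InterpolationParams()
    if len(series) < 3:
        raise ValueError("interpolation requires >= 3 input points")
    pos = series.positions
    span = pos[-1] - pos[0]
    if span <= 0:
        raise ValueError("degenerate position range")
    t_in = (pos - pos[0]) / span
    grid = np.linspace(0.0, 1.0, params.num_pts)
    # (num_pts, n) weight matrix; winsz in (0,1] keeps exponents well-scaled
    w = np.exp(-((grid[:, None] - t_in[None, :]) ** 2) / (2.0 * params.winsz**2))
    out = (w @ series.values) / w.sum(axis=1)
    return OrderedSeries(grid, out, label=series.label)


def interaction_series_paracrine(
    ligand_interp: OrderedSeries, receptor_interp: OrderedSeries
) -> OrderedSeries:
    """Pointwise product of interpolated sender-ligand and receiver-receptor signals.

    The grid-level analogue of the cell-type-level interaction score
    (mean ligand expression x mean receptor expression).
    """
    if not ligand_interp.same_grid(receptor_interp):
        raise ValueError("ligand and receptor series are on different grids")
    vals = ligand_interp.values * receptor_interp.values
    return OrderedSeries(
        ligand_interp.positions.copy(),
        vals,
        label=f"IS({ligand_interp.label},{receptor_interp.label})",
    )
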