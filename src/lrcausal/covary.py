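"""Screen LR pairs for co-variation along the ordering.

Autocrine mode correlates the ligand and receptor expression series over
ordered cells (Pearson, cutoff ``|PCC| > 0.1`` by default).  Paracrine mode
correlates interpolated ligand (sender lineage) and receptor (receiver
lineage) signals on a common grid (Spearman, cutoff ``SCC > 0.2``).

The default 0.1 autocrine cutoff was originally derived by a double-tangent
construction on the ranked positive-PCC curve; :func:`derive_cutoff`
reimplements that construction so users can recompute it on their own data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .datatypes import ExpressionMatrix, InterpolationParams, LRPair, OrderedSeries
from .ordering import cell_series, interpolate

logger = logging.getLogger(__name__)

__all__ = ["CovaryResult", "screen_covarying", "screen_covarying_paracrine", "derive_cutoff"]


@dataclass
class CovaryResult:
    pair: LRPair
    pcc: float
    scc: float
    passed: bool
    mode: str                     # "autocrine" | "paracrine"
    constant: bool = False        # correlation undefined, recorded as 0
    self_pair: bool = False


def _safe_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """(pearson, spearman, constant_flag); constant series give (0, 0, True)."""
    if np.std(x) < 1e-15 or np.std(y) < 1e-15:
        return 0.0, 0.0, True
    pcc = float(scipy.stats.pearsonr(x, y).statistic)
    scc = float(scipy.stats.spearmanr(x, y).statistic)
    return pcc, scc, False


def screen_covarying(
    mat: ExpressionMatrix,
    ordering: list[str],
    lr_db: list[LRPair],
    cutoff: float = 0.1,
) -> list[CovaryResult]:
    """Autocrine co-variation screen: |PCC| > cutoff over ordered cells.

    Pairs whose ligand or receptor is absent from the matrix are skipped
    (counted in a log line); constant series yield correlation 0, flagged.
    """
    if not lr_db:
        raise ValueError("empty LR database")
    if len(ordering) < 3:
        raise ValueError("need >= 3 ordered cells")
    results: list[CovaryResult] = []
    n_skipped = 0
    for pair in lr_db:
        if pair.ligand not in mat or pair.receptor not in mat:
            n_skipped += 1
            continue
        lig = mat.gene_over(pair.ligand, ordering)
        rec = mat.gene_over(pair.receptor, ordering)
        pcc, scc, const = _safe_corr(lig, rec)
        results.append(
            CovaryResult(
                pair=pair,
                pcc=pcc,
                scc=scc,
                passed=(not const) and abs(pcc) > cutoff,
                mode="autocrine",
                constant=const,
                self_pair=pair.is_self_pair,
            )
        )
    if n_skipped:
        logger.info("screen: skipped %d pairs with genes absent from matrix", n_skipped)
    return results


def screen_covarying_paracrine(
    sender_mat: ExpressionMatrix,
    sender_ordering: list[str],
    sender_positions: np.ndarray,
    receiver_mat: ExpressionMatrix,
    receiver_ordering: list[str],
    receiver_positions: np.ndarray,
    lr_db: list[LRPair],
    params: InterpolationParams | None = None,
    cutoff: float = 0.2,
) -> tuple[list[CovaryResult], dict[LRPair, OrderedSeries]]:
    """Paracrine screen: Spearman of interpolated ligand/receptor signals > cutoff.

    Ligand expression comes from the sender lineage, receptor expression from
    the receiver lineage; both are interpolated onto the same uniform grid
    before correlating.  Returns the screen results together with the
    interaction-score series (pointwise product) for every evaluated pair.
    """
    from .ordering import interaction_series_paracrine

    if not lr_db:
        raise ValueError("empty LR database")
    params = params or InterpolationParams()
    results: list[CovaryResult] = []
    is_series: dict[LRPair, OrderedSeries] = {}
    n_skipped = 0
    lig_cache: dict[str, OrderedSeries] = {}
    rec_cache: dict[str, OrderedSeries] = {}
    for pair in lr_db:
        if pair.ligand not in sender_mat or pair.receptor not in receiver_mat:
            n_skipped += 1
            continue
        if pair.ligand not in lig_cache:
            lig_cache[pair.ligand] = interpolate(
                cell_series(sender_mat, sender_ordering, pair.ligand, sender_positions), params
            )
        if pair.receptor not in rec_cache:
            rec_cache[pair.receptor] = interpolate(
                cell_series(receiver_mat, receiver_ordering, pair.receptor, receiver_positions),
                params,
            )
        lig_i, rec_i = lig_cache[pair.ligand], rec_cache[pair.receptor]
        pcc, scc, const = _safe_corr(lig_i.values, rec_i.values)
        results.append(
            CovaryResult(
                pair=pair,
                pcc=pcc,
                scc=scc,
                passed=(not const) and scc > cutoff,
                mode="paracrine",
                constant=const,
                self_pair=pair.is_self_pair,
            )
        )
        is_series[pair] = interaction_series_paracrine(lig_i, rec_i)
    if n_skipped:
        logger.info("paracrine screen: skipped %d pairs with missing genes", n_skipped)
    return results, is_series


def _perp_distances(x: np.ndarray, y: np.ndarray, i0: int, i1: int) -> np.ndarray:
    """Unsigned perpendicular distance of every point from chord (i0, i1)."""
    dx, dy = x[i1] - x[i0], y[i1] - y[i0]
    norm = np.hypot(dx, dy)
    if norm < 1e-300:
        return np.zeros_like(x)
    return np.abs(dy * (x - x[i0]) - dx * (y - y[i0])) / norm


def derive_cutoff(pccs: np.ndarray, side: str = "positive", tol: float = 1e-12) -> float:
    """Double-tangent cutoff on the ranked-correlation curve.

    Rank the correlations of the requested sign ascending; with A the first
    and B the last curve point, C is the point of maximal perpendicular
    distance from chord AB, and D the point of maximal perpendicular distance
    from chord AC (searched between A and C).  The returned cutoff is the
    ordinate (correlation value) of D.  For ``side="negative"`` the procedure
    runs on mirrored values and the sign is restored.  Ties break toward the
    smaller rank index.
    """
    pccs = np.asarray(pccs, dtype=float)
    if side == "positive":
        vals = np.sort(pccs[pccs > 0])
        sign = 1.0
    elif side == "negative":
        vals = np.sort(-pccs[pccs < 0])
        sign = -1.0
    else:
        raise ValueError("side must be 'positive' or 'negative'")
    if len(vals) < 10:
        raise ValueError(f"need >= 10 {side} correlations, got {len(vals)}")
    x = np.arange(len(vals), dtype=float)
    d_ab = _perp_distances(x, vals, 0, len(vals) - 1)
    if d_ab.max() <= tol:
        raise ValueError(
            "ranked curve is linear (all points on chord AB); set the cutoff manually"
        )
    c = int(np.argmax(d_ab))                      # argmax takes first maximum: smaller rank
    d_ac = _perp_distances(x[: c + 1], vals[: c + 1], 0, c)
    d = int(np.argmax(d_ac))
    return sign * float(vals[d])
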