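"""Readers/writers for the package's plain-text formats and basic preprocessing.

Formats
-------
* Dense TSV: first column gene symbol, header row of cell ids, tab separated.
* MatrixMarket coordinate (.mtx) with ``genes.txt`` / ``barcodes.txt`` sidecars.
* LR database: TSV with ligand/receptor symbol columns (CellTalkDB layout).
* Gene sets: one symbol per line.

Normalization is the caller's responsibility.  The reference analysis used
RPKM and log10(RPKM + 1); :func:`log_normalize` and :func:`quantile_normalize`
are provided as optional helpers and are not wired into any pipeline stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.linalg
import scipy.sparse

from .datatypes import CellMetadata, ExpressionMatrix, GeneSet, LRPair

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_lr_database",
    "read_gene_set",
    "read_metadata",
    "pseudo_bulk",
    "log_normalize",
    "quantile_normalize",
    "impute_zero_preserving",
]


def _collapse_duplicate_genes(df: pd.DataFrame) -> pd.DataFrame:
    # keep the duplicate row with maximal total expression (deterministic)
    if df.index.is_unique:
        return df
    totals = df.sum(axis=1).to_numpy()
    # sort by -total (stable), dedup keeping first => max-total row per symbol
    tagged = df.assign(__total=totals).sort_values("__total", ascending=False, kind="stable")
    tagged = tagged[~tagged.index.duplicated(keep="first")].drop(columns="__total")
    dropped = len(df) - len(tagged)
    logger.warning("collapsed %d duplicate gene rows (kept max-total row per symbol)", dropped)
    # preserve first-appearance order of the surviving symbols
    first_order = df.index[~df.index.duplicated(keep="first")]
    return tagged.loc[first_order]


def read_expression(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a genes x cells expression matrix.

    ``format`` is ``"tsv"`` (dense, genes as rows, header of cell ids) or
    ``"mtx"`` (MatrixMarket coordinate file with ``genes.txt`` and
    ``barcodes.txt`` sidecars in the same directory).  Duplicate gene symbols
    are collapsed by keeping the row with maximal total expression.
    """
    path = Path(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed expression TSV {path}: {exc}") from exc
        df.index = df.index.astype(str)
        df = _collapse_duplicate_genes(df)
        return ExpressionMatrix.from_frame(df)
    if format == "mtx":
        mat = scipy.io.mmread(path).toarray().astype(float)
        genes = [l.strip() for l in (path.parent / "genes.txt").read_text().splitlines() if l.strip()]
        cells = [l.strip() for l in (path.parent / "barcodes.txt").read_text().splitlines() if l.strip()]
        if mat.shape != (len(genes), len(cells)):
            raise ValueError(
                f"MTX dimensions {mat.shape} do not match sidecars "
                f"({len(genes)} genes, {len(cells)} barcodes)"
            )
        df = _collapse_duplicate_genes(pd.DataFrame(mat, index=genes, columns=cells))
        return ExpressionMatrix.from_frame(df)
    raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")


def write_expression(mat: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix in a format :func:`read_expression` accepts."""
    path = Path(path)
    if format == "tsv":
        mat.to_frame().to_csv(path, sep="\t")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(mat.values))
        (path.parent / "genes.txt").write_text("\n".join(mat.gene_ids) + "\n")
        (path.parent / "barcodes.txt").write_text("\n".join(mat.cell_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_lr_database(
    path: str | Path,
    ligand_col: str = "ligand_gene_symbol",
    receptor_col: str = "receptor_gene_symbol",
) -> list[LRPair]:
    """Read a CellTalkDB-style ligand-receptor table.

    Pairs are deduplicated preserving original order; rows with an empty
    ligand or receptor are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (ligand_col, receptor_col):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not found in LR database; available: {list(df.columns)}"
            )
    pairs: list[LRPair] = []
    seen: set[tuple[str, str]] = set()
    n_bad = 0
    for lig, rec in zip(df[ligand_col], df[receptor_col]):
        lig = "" if pd.isna(lig) else str(lig).strip()
        rec = "" if pd.isna(rec) else str(rec).strip()
        if not lig or not rec:
            n_bad += 1
            continue
        if (lig, rec) in seen:
            continue
        seen.add((lig, rec))
        pairs.append(LRPair(lig, rec))
    if n_bad:
        logger.warning("dropped %d LR rows with empty ligand or receptor", n_bad)
    return pairs


def read_gene_set(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene set file."""
    path = Path(path)
    members = [l.strip() for l in path.read_text().splitlines() if l.strip()]
    return GeneSet(name or path.stem, members)


def read_metadata(path: str | Path, stage_order: list[str]) -> CellMetadata:
    """Read a per-cell metadata TSV (index: cell id; columns incl. ``stage``)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    return CellMetadata(table, stage_order)


def pseudo_bulk(mat: ExpressionMatrix, meta: CellMetadata, group_by: str = "stage") -> ExpressionMatrix:
    """Average expression per metadata group ("pseudo-bulk for an average cell").

    Output column order follows the declared stage order when grouping by
    stage, otherwise first appearance.  Empty groups are excluded.
    """
    if group_by not in meta.table.columns:
        raise KeyError(f"{group_by!r} is not a metadata column")
    meta.check_against(mat)
    groups = meta.table[group_by].astype(str)
    if group_by == "stage":
        order = [s for s in meta.stage_order if (groups == s).any()]
        skipped = [s for s in meta.stage_order if not (groups == s).any()]
        if skipped:
            logger.warning("pseudo_bulk: empty groups excluded: %s", skipped)
    else:
        order = list(dict.fromkeys(groups))
    cols = []
    for g in order:
        cells = list(groups.index[groups == g])
        cols.append(mat.subset_cells(cells).values.mean(axis=1))
    return ExpressionMatrix(np.column_stack(cols), list(mat.gene_ids), order)


def log_normalize(mat: ExpressionMatrix, base: float = 10.0, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log(x + pseudocount); the reference analysis used log10(RPKM + 1)."""
    if np.any(mat.values < 0):
        raise ValueError("log_normalize expects non-negative input")
    vals = np.log(mat.values + pseudocount) / np.log(base)
    return ExpressionMatrix(vals, list(mat.gene_ids), list(mat.cell_ids))


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to a common (mean-of-sorted) distribution.

    Optional helper; not part of any pipeline stage.
    """
    vals = mat.values
    order = np.argsort(vals, axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(vals.shape[0])[:, None], axis=0)
    reference = np.sort(vals, axis=0).mean(axis=1)
    out = reference[ranks]
    return ExpressionMatrix(out, list(mat.gene_ids), list(mat.cell_ids))


def _auto_rank(s: np.ndarray) -> int:
    """Signal rank from the singular-value spacings.

    Noise singular values are tightly spaced; signal components separate.
    The rank is the last of the top 50 components whose spacing to the next
    exceeds the noise floor (mean + 6 sd of the tail spacings).
    """
    top = s[: min(50, len(s))]
    if len(top) < 3:
        return 1
    d = -np.diff(top)
    tail = d[len(d) // 2 :]
    thresh = tail.mean() + 6.0 * tail.std()
    sig = np.nonzero(d > thresh)[0]
    return int(sig.max() + 1) if len(sig) else 1


def impute_zero_preserving(mat: ExpressionMatrix, rank: int | str = "auto") -> ExpressionMatrix:
    """Zero-preserving low-rank imputation of a (log-scale) expression matrix.

    Mirrors the ALRA idea: reconstruct the matrix at low rank, then for each
    gene zero every reconstructed entry whose magnitude falls below that
    gene's most-negative reconstructed value (in absolute value) — the
    rationale being that symmetric-around-zero reconstruction error marks the
    noise floor — and affine-rescale the surviving nonzero entries to the
    original nonzero mean/sd of the gene.  Values are clamped at zero;
    all-zero genes are returned unchanged; shape never changes.
    """
    X = mat.values
    n_min = min(X.shape)
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False)
    if rank == "auto":
        k = _auto_rank(s)
    else:
        k = int(rank)
        if k < 1:
            raise ValueError("rank must be >= 1")
        if k >= n_min:
            raise ValueError(f"rank must be < min(matrix dims) = {n_min}")
    recon = (U[:, :k] * s[:k]) @ Vt[:k]

    out = recon.copy()
    for i in range(X.shape[0]):
        orig = X[i]
        if not np.any(orig != 0):
            out[i] = 0.0
            continue
        row = recon[i]
        row_min = row.min()
        thresh = abs(row_min) if row_min < 0 else 0.0
        keep = np.abs(row) > thresh if thresh > 0 else np.ones_like(row, bool)
        row = np.where(keep, row, 0.0)
        surv = row != 0
        if surv.any():
            nz = orig[orig != 0]
            m_o, s_o = nz.mean(), nz.std()
            m_r, s_r = row[surv].mean(), row[surv].std()
            if s_r > 1e-12 and s_o > 1e-12:
                row[surv] = (row[surv] - m_r) / s_r * s_o + m_o
            else:
                row[surv] = row[surv] - m_r + m_o
        out[i] = np.clip(row, 0.0, None)
    return ExpressionMatrix(out, list(mat.gene_ids), list(mat.cell_ids))
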