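"""Core in-memory containers shared by every stage of the pipeline.

The unit of analysis is a genes x cells expression matrix plus per-cell
metadata carrying an explicitly declared stage order.  All time-series
machinery downstream operates on :class:`OrderedSeries` objects: a scalar
signal indexed by a strictly increasing position vector (pseudotime rank or
an interpolation grid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CellMetadata",
    "LRPair",
    "GeneSet",
    "OrderedSeries",
    "InterpolationParams",
]


@dataclass
class ExpressionMatrix:
    """Normalized expression, genes as rows, cells as columns.

    Values are expected to be finite and non-negative (pre-log counts/RPKM)
    or at least finite (post-log).  Gene and cell identifiers must be unique
    and match the matrix dimensions.
    """

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        ng, nc = self.values.shape
        if ng != len(self.gene_ids) or nc != len(self.cell_ids):
            raise ValueError(
                f"dimension mismatch: values {self.values.shape} vs "
                f"{len(self.gene_ids)} genes / {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._cell_index = {c: i for i, c in enumerate(self.cell_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self._gene_index

    def gene(self, gene: str) -> np.ndarray:
        """Expression of one gene across all cells, in stored cell order."""
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def gene_over(self, gene: str, cell_ids: Sequence[str]) -> np.ndarray:
        """Expression of one gene over an explicit cell ordering."""
        row = self.gene(gene)
        idx = [self._cell_index[c] for c in cell_ids]
        return row[idx]

    def subset_cells(self, cell_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._cell_index[c] for c in cell_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(cell_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index.astype(str)), list(df.columns.astype(str)))


@dataclass
class CellMetadata:
    """Per-cell annotation with an explicitly declared stage order.

    ``table`` is indexed by cell id and carries columns ``stage``,
    ``pseudotime`` (NaN when missing) and optionally ``cell_type``.
    The stage order is declared, never inferred from string sort.
    """

    table: pd.DataFrame
    stage_order: list[str]

    def __post_init__(self) -> None:
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        if "stage" not in self.table.columns:
            raise ValueError("metadata requires a 'stage' column")
        if "pseudotime" not in self.table.columns:
            self.table["pseudotime"] = np.nan
        self.stage_order = [str(s) for s in self.stage_order]
        if len(set(self.stage_order)) != len(self.stage_order):
            raise ValueError("duplicate stage in stage_order")
        seen = set(self.table["stage"].astype(str))
        missing = seen - set(self.stage_order)
        if missing:
            raise ValueError(f"stages not declared in stage_order: {sorted(missing)}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def check_against(self, mat: ExpressionMatrix) -> None:
        missing = [c for c in self.cell_ids if c not in mat._cell_index]
        if missing:
            raise ValueError(f"{len(missing)} metadata cells absent from matrix, e.g. {missing[:3]}")

    def with_pseudotime(self, pseudotime: pd.Series) -> "CellMetadata":
        table = self.table.copy()
        table["pseudotime"] = pseudotime.reindex(table.index)
        return CellMetadata(table, list(self.stage_order))


@dataclass(frozen=True, order=True)
class LRPair:
    """A ligand-receptor gene pair (mouse symbols in the reference analysis)."""

    ligand: str
    receptor: str

    def __post_init__(self) -> None:
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor symbols must be non-empty")

    @property
    def is_self_pair(self) -> bool:
        return self.ligand == self.receptor

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.ligand}-{self.receptor}"


@dataclass
class GeneSet:
    """A named collection of gene symbols."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members: Iterable[str]):
        if not name:
            raise ValueError("gene set name must be non-empty")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(str(m) for m in members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


@dataclass
class OrderedSeries:
    """A scalar signal along an ordering: positions strictly increase.

    Positions are pseudotime values, integer ranks, or interpolation-grid
    coordinates; ties in raw pseudotime must be broken before construction.
    """

    positions: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.ndim != 1 or self.values.ndim != 1:
            raise ValueError("positions and values must be 1-D")
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values length mismatch")
        if len(self.positions) >= 2 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)

    def same_grid(self, other: "OrderedSeries", atol: float = 1e-12) -> bool:
        return len(self) == len(other) and np.allclose(self.positions, other.positions, atol=atol)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "OrderedSeries":
        return OrderedSeries(self.positions.copy(), values, self.label if label is None else label)


@dataclass(frozen=True)
class InterpolationParams:
    """Gaussian-kernel interpolation settings.

    ``winsz`` is the kernel bandwidth on pseudotime rescaled to [0, 1];
    ``num_pts`` is the uniform output grid size.  Defaults follow the
    reference analysis (winsz 0.1, 200 points).
    """

    winsz: float = 0.1
    num_pts: int = 200

    def __post_init__(self) -> None:
        if not (0 < self.winsz <= 1):
            raise ValueError("winsz must lie in (0, 1]")
        if self.num_pts < 10:
            raise ValueError("num_pts must be >= 10")
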