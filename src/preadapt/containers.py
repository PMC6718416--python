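"""Core in-memory containers shared across the pipeline.

The central container is :class:`CountMatrix`, a genes x cells sparse UMI
count matrix with gene and cell identifiers, mirroring the 10x Genomics
MatrixMarket triple it is read from and written to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers.

    Parameters
    ----------
    matrix
        ``scipy.sparse`` matrix of shape ``(n_genes, n_cells)`` holding
        non-negative integer counts.
    gene_ids
        One identifier per row, unique.
    cell_ids
        One barcode per column, unique.
    """

    matrix: sp.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.matrix.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene identifiers must be unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell identifiers must be unique")

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())

    def subset_genes(self, keep: np.ndarray | list) -> "CountMatrix":
        """Return a new matrix keeping the given gene rows (mask or indices)."""
        idx = _as_index(keep, self.n_genes)
        return CountMatrix(self.matrix[idx, :], [self.gene_ids[i] for i in idx], self.cell_ids)

    def subset_cells(self, keep: np.ndarray | list) -> "CountMatrix":
        """Return a new matrix keeping the given cell columns (mask or indices)."""
        idx = _as_index(keep, self.n_cells)
        return CountMatrix(self.matrix[:, idx], self.gene_ids, [self.cell_ids[i] for i in idx])

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError as exc:
            raise KeyError(f"gene {gene_id!r} not present") from exc


@dataclass
class NormalizedMatrix:
    """Dense genes x cells matrix of log-normalised expression values."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError("values shape does not match identifier lengths")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)

    def subset_genes(self, keep) -> "NormalizedMatrix":
        idx = _as_index(keep, self.n_genes)
        return NormalizedMatrix(self.values[idx, :], [self.gene_ids[i] for i in idx], self.cell_ids)

    def subset_cells(self, keep) -> "NormalizedMatrix":
        idx = _as_index(keep, self.n_cells)
        return NormalizedMatrix(self.values[:, idx], self.gene_ids, [self.cell_ids[i] for i in idx])


@dataclass
class GeneSet:
    """A named gene set, optionally signed (``direction`` in {'up', 'down'})."""

    name: str
    genes: list[str]
    direction: str | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        # preserve order, drop duplicates
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g, None)
        self.genes = list(seen)

    def __len__(self) -> int:
        return len(self.genes)


def _as_index(keep, n: int) -> np.ndarray:
    keep = np.asarray(keep)
    if keep.dtype == bool:
        if keep.shape != (n,):
            raise ValueError("boolean mask length mismatch")
        return np.flatnonzero(keep)
    return keep.astype(int)
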