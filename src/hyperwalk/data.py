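"""Expression matrix container and on-disk exchange formats.

The package's central object is a gene x cell matrix of non-negative
expression values.  On disk it travels either as a Matrix Market sparse
triple (``matrix.mtx`` + ``genes.tsv`` + ``barcodes.tsv``, the CellRanger
convention with genes as rows) or as a dense CSV with gene IDs in the first
column and cell IDs in the header.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["ExpressionMatrix", "read_matrix", "write_matrix", "read_labels", "write_labels"]


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix of non-negative expression values.

    Parameters
    ----------
    values
        2-D array or scipy sparse matrix, shape ``(n_genes, n_cells)``.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    """

    values: sp.spmatrix | np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = self.values.tocsr()
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ValueError("expression values must be 2-D (genes x cells)")
        n_genes, n_cells = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i}" for i in range(n_genes)]
        if not self.cell_ids:
            self.cell_ids = [f"cell_{j}" for j in range(n_cells)]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != n_genes:
            raise ValueError(f"{len(self.gene_ids)} gene IDs for {n_genes} rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError(f"{len(self.cell_ids)} cell IDs for {n_cells} columns")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene IDs")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell IDs")
        if self.min() < 0:
            raise ValueError("expression values must be non-negative")

    # -- basic queries -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def min(self) -> float:
        if sp.issparse(self.values):
            return float(self.values.data.min()) if self.values.nnz else 0.0
        return float(self.values.min()) if self.values.size else 0.0

    def dense(self) -> np.ndarray:
        """Return the values as a dense float ndarray (copy for sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def sparsity(self) -> float:
        """Fraction of exactly-zero entries."""
        total = self.n_genes * self.n_cells
        if total == 0:
            return 0.0
        nnz = self.values.nnz if sp.issparse(self.values) else int(np.count_nonzero(self.values))
        return 1.0 - nnz / total

    def subset(self, gene_idx=None, cell_idx=None) -> "ExpressionMatrix":
        """Row/column subset preserving ID correspondence."""
        v = self.values
        genes = self.gene_ids
        cells = self.cell_ids
        if gene_idx is not None:
            gene_idx = np.asarray(gene_idx)
            v = v[gene_idx, :]
            genes = [genes[i] for i in gene_idx]
        if cell_idx is not None:
            cell_idx = np.asarray(cell_idx)
            v = v[:, cell_idx]
            cells = [cells[j] for j in cell_idx]
        return ExpressionMatrix(v, genes, cells)


def read_matrix(path: str, genes: str | None = None, barcodes: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from ``.mtx`` (+ ID TSVs) or dense CSV.

    For ``.mtx`` input, ``genes`` and ``barcodes`` default to ``genes.tsv``
    and ``barcodes.tsv`` next to the matrix file.
    """
    if path.endswith(".mtx"):
        base = os.path.dirname(path)
        genes = genes or os.path.join(base, "genes.tsv")
        barcodes = barcodes or os.path.join(base, "barcodes.tsv")
        values = sp.csr_matrix(mmread(path))
        gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str).tolist()
        cell_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        return ExpressionMatrix(values, gene_ids, cell_ids)
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float), df.index.astype(str).tolist(), df.columns.astype(str).tolist())


def write_matrix(m: ExpressionMatrix, path: str) -> None:
    """Write to ``.mtx`` (+ genes.tsv/barcodes.tsv beside it) or dense CSV."""
    if path.endswith(".mtx"):
        base = os.path.dirname(path)
        if base:
            os.makedirs(base, exist_ok=True)
        mmwrite(path, sp.coo_matrix(m.values))
        pd.Series(m.gene_ids).to_csv(os.path.join(base, "genes.tsv"), sep="\t", header=False, index=False)
        pd.Series(m.cell_ids).to_csv(os.path.join(base, "barcodes.tsv"), sep="\t", header=False, index=False)
    else:
        pd.DataFrame(m.dense(), index=m.gene_ids, columns=m.cell_ids).to_csv(path)


def read_labels(path: str) -> pd.Series:
    """Read a two-column (id <TAB> label) TSV into a Series indexed by id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"])
    return pd.Series(df["label"].to_numpy(), index=df["id"].astype(str))


def write_labels(ids, labels, path: str) -> None:
    base = os.path.dirname(path)
    if base:
        os.makedirs(base, exist_ok=True)
    pd.DataFrame({"id": ids, "label": labels}).to_csv(path, sep="\t", header=False, index=False)
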