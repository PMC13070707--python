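"""Count-matrix preprocessing: zero filtering, CPM, log, HVG selection.

The canonical order is ``drop_zero -> cpm_normalize -> log_transform``
followed (for real data) by highly-variable-gene selection; ``preprocess``
wires the pipeline in that order.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .data import ExpressionMatrix

__all__ = ["drop_zero", "cpm_normalize", "log_transform", "select_hvg", "preprocess"]


def drop_zero(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove genes and cells with zero total expression (to fixpoint)."""
    out = m
    while True:
        v = out.values
        row_sums = np.asarray(v.sum(axis=1)).ravel()
        col_sums = np.asarray(v.sum(axis=0)).ravel()
        keep_g = np.flatnonzero(row_sums > 0)
        keep_c = np.flatnonzero(col_sums > 0)
        if keep_g.size == 0 or keep_c.size == 0:
            raise ValueError("all rows or columns have zero total expression")
        if keep_g.size == out.n_genes and keep_c.size == out.n_cells:
            return out
        out = out.subset(keep_g, keep_c)


def cpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each cell so its column total is one million (CPM)."""
    col_sums = np.asarray(m.values.sum(axis=0)).ravel()
    if np.any(col_sums == 0):
        bad = [m.cell_ids[j] for j in np.flatnonzero(col_sums == 0)[:5]]
        raise ValueError(f"cells with zero total expression (e.g. {bad}); run drop_zero first")
    scale = 1e6 / col_sums
    if sp.issparse(m.values):
        v = m.values @ sp.diags(scale)
    else:
        v = m.values * scale[None, :]
    return ExpressionMatrix(v, m.gene_ids, m.cell_ids)


def log_transform(m: ExpressionMatrix, base: float | None = None) -> ExpressionMatrix:
    """Apply ``log(1 + x)`` entrywise; zeros stay zero.

    Natural log by default; pass ``base`` for another logarithm base.
    """
    if m.min() < 0:
        raise ValueError("log transform requires non-negative entries")
    if sp.issparse(m.values):
        v = m.values.copy()
        v.data = np.log1p(v.data)
    else:
        v = np.log1p(m.values)
    if base is not None:
        v = v / np.log(base)
    return ExpressionMatrix(v, m.gene_ids, m.cell_ids)


def select_hvg(m: ExpressionMatrix, n: int, n_bins: int = 20) -> ExpressionMatrix:
    """Retain the top ``n`` highly variable genes (Seurat-flavour dispersion).

    Per-gene dispersion (variance / mean) is z-scored within equal-frequency
    bins of the gene mean, and the ``n`` genes with the highest normalised
    dispersion are kept, in their original order.
    """
    if n > m.n_genes:
        raise ValueError(f"requested {n} HVGs but matrix has {m.n_genes} genes")
    if n == m.n_genes:
        return m
    X = m.dense()
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    n_bins = min(n_bins, m.n_genes)
    # equal-frequency bins of the mean
    order = np.argsort(mean, kind="stable")
    bins = np.empty(m.n_genes, dtype=int)
    bins[order] = np.minimum((np.arange(m.n_genes) * n_bins) // m.n_genes, n_bins - 1)
    z = np.zeros(m.n_genes)
    for b in range(n_bins):
        mask = bins == b
        if not mask.any():
            continue
        d = disp[mask]
        sd = d.std()
        z[mask] = (d - d.mean()) / sd if sd > 0 else 0.0
    # ties in normalised dispersion (e.g. singleton bins) break on raw dispersion
    order = np.lexsort((-disp, -z))
    top = np.sort(order[:n])
    return m.subset(gene_idx=top)


def preprocess(m: ExpressionMatrix, hvg: int | None = None, log_base: float | None = None) -> ExpressionMatrix:
    """Full pipeline: drop_zero -> CPM -> log -> (optional) HVG."""
    out = log_transform(cpm_normalize(drop_zero(m)), base=log_base)
    if hvg is not None:
        out = select_hvg(out, hvg)
    return out
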