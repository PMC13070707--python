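"""Cell and gene co-expression networks, and the sparsity-inflation experiment.

Similarity networks are dense symmetric Spearman-correlation matrices over
cells (columns) or genes (rows) of a preprocessed expression matrix.
Negative correlations are clipped to zero by default so the entries can act
as probability factors in memory-integrated walks; diagonals are zeroed to
force non-lazy walks.

``inflation_experiment`` demonstrates why shared zeros are dangerous when
building such networks from sparse data: appending common zeros to two
independent expression profiles drives their sample correlation towards 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data import ExpressionMatrix

__all__ = ["SimilarityNetwork", "spearman_network", "non_lazy", "inflation_experiment"]


@dataclass
class SimilarityNetwork:
    """Symmetric non-negative similarity matrix over cells or genes."""

    values: np.ndarray
    ids: list[str]
    kind: str  # "cell" | "gene"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if len(self.ids) != self.values.shape[0]:
            raise ValueError("ID count must match matrix size")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def spearman_network(
    m: ExpressionMatrix,
    kind: str = "cell",
    negative: str = "clip",
) -> SimilarityNetwork:
    """Pairwise Spearman correlation network over cells or genes.

    Parameters
    ----------
    kind
        ``"cell"`` correlates columns, ``"gene"`` correlates rows.
    negative
        ``"clip"`` maps negative correlations to 0 (default), ``"abs"``
        takes absolute values.

    Constant profiles have undefined rank correlation; their similarities
    are set to 0 with a warning.  The diagonal is zeroed (non-lazy).
    """
    if kind not in ("cell", "gene"):
        raise ValueError("kind must be 'cell' or 'gene'")
    X = m.dense()
    if kind == "cell":
        profiles = X  # columns are variables
        ids = m.cell_ids
    else:
        profiles = X.T
        ids = m.gene_ids
    if profiles.shape[1] < 2:
        raise ValueError("need at least 2 entities to correlate")
    if profiles.shape[0] < 3:
        raise ValueError("need at least 3 observations per entity")
    rho = spearmanr(profiles, axis=0).statistic
    if np.ndim(rho) == 0:  # spearmanr collapses the 2-entity case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    rho = np.asarray(rho, dtype=float)
    if np.isnan(rho).any():
        warnings.warn("constant profiles encountered; their similarities set to 0", stacklevel=2)
        rho = np.nan_to_num(rho, nan=0.0)
    if negative == "clip":
        rho = np.clip(rho, 0.0, None)
    elif negative == "abs":
        rho = np.abs(rho)
    else:
        raise ValueError("negative must be 'clip' or 'abs'")
    np.fill_diagonal(rho, 0.0)
    rho = (rho + rho.T) / 2.0  # enforce exact symmetry
    return SimilarityNetwork(rho, list(ids), kind)


def non_lazy(g: SimilarityNetwork) -> SimilarityNetwork:
    """Zero the diagonal so consecutive walk steps cannot stay in place."""
    v = g.values.copy()
    np.fill_diagonal(v, 0.0)
    return SimilarityNetwork(v, list(g.ids), g.kind)


def inflation_experiment(
    base_length: int = 50,
    zero_fractions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    n_reps: int = 100,
    seed: int = 0,
    base_lambda: float = 5.0,
) -> pd.DataFrame:
    """Measure correlation inflation from shared appended zeros.

    For each zero fraction ``f``, draws ``n_reps`` pairs of independent
    Poisson(base_lambda) profiles of length ``base_length``, appends enough
    shared zeros that added zeros make up fraction ``f`` of the profile, and
    records Pearson and Spearman correlations.  Returns a tidy frame with
    one row per (fraction, statistic): mean correlation with a 95%
    normal-approximation CI.  The ``f = 0`` row is the baseline correlation
    without added sparsity.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    fracs = sorted(set(float(f) for f in zero_fractions))
    if any(f < 0 or f >= 1 for f in fracs):
        raise ValueError("zero fractions must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for f in fracs:
        n_zeros = int(round(base_length * f / (1.0 - f)))
        pearson = np.empty(n_reps)
        spear = np.empty(n_reps)
        for i in range(n_reps):
            a = rng.poisson(base_lambda, base_length).astype(float)
            b = rng.poisson(base_lambda, base_length).astype(float)
            if n_zeros:
                z = np.zeros(n_zeros)
                a = np.concatenate([a, z])
                b = np.concatenate([b, z])
            with np.errstate(invalid="ignore"):
                pearson[i] = np.corrcoef(a, b)[0, 1]
                spear[i] = spearmanr(a, b).statistic
        pearson = np.nan_to_num(pearson, nan=0.0)
        spear = np.nan_to_num(spear, nan=0.0)
        for stat, vals in (("pearson", pearson), ("spearman", spear)):
            se = vals.std(ddof=1) / np.sqrt(n_reps)
            rows.append({
                "fraction": f,
                "statistic": stat,
                "mean_corr": vals.mean(),
                "ci_low": vals.mean() - 1.96 * se,
                "ci_high": vals.mean() + 1.96 * se,
            })
    return pd.DataFrame(rows)
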