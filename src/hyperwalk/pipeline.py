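"""End-to-end orchestration: single runs, the PCA baseline, modularity sweeps.

A run chains preprocess -> (co-expression networks if the method needs
memory) -> hypergraph -> transition kernel -> walk sampling -> skip-gram
embedding -> K-means, and scores against ground truth when available.  One
master seed deterministically derives the per-stage seeds so stages can be
re-run in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .coexpression import spearman_network
from .data import ExpressionMatrix
from .embedding import ClusterLabels, Embedding, kmeans_cluster, train_embedding
from .evaluation import EvalReport, score
from .hypergraph import (
    WalkParams, build_hypergraph, comem_transition, diphw_transition,
    edvw_transition, sample_walks,
)
from .preprocess import preprocess
from .simulate import SimulationConfig, barber_modularity, simulate

logger = logging.getLogger("hyperwalk")

__all__ = ["RunConfig", "METHODS", "run_pipeline", "pca_kmeans_baseline",
           "modularity_sweep", "paper_like_profile"]

METHODS = ("edvw", "diphw", "comem", "comem-diphw", "pca-kmeans")


@dataclass
class RunConfig:
    """Configuration for one end-to-end clustering run."""

    method: str = "diphw"
    K: int = 10
    alpha: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    dim: int = 64
    window: int = 5
    epochs: int = 10
    neg_samples: int = 5
    n_init: int = 10
    hvg: int | None = None
    similarity_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


def _stage_seeds(master: int) -> dict[str, int]:
    """Derive independent per-stage seeds from one master seed."""
    ss = np.random.SeedSequence(master)
    names = ("simulate", "walks", "embedding", "kmeans")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in zip(names, children)}


def embed_cells(m: ExpressionMatrix, cfg: RunConfig) -> Embedding:
    """Preprocessed matrix -> cell embedding with the configured method."""
    seeds = _stage_seeds(cfg.seed)
    if cfg.method == "pca-kmeans":
        raise ValueError("pca-kmeans has no walk embedding; use pca_kmeans_baseline")
    h = build_hypergraph(m)
    if cfg.method == "diphw":
        P = diphw_transition(h, cfg.alpha)
    elif cfg.method == "edvw":
        P = edvw_transition(h)
    else:
        g_v = spearman_network(m, kind="cell")
        g_e = spearman_network(m, kind="gene")
        P = comem_transition(h, g_v, g_e, mode=cfg.method, alpha=cfg.alpha,
                             similarity_floor=cfg.similarity_floor)
    params = WalkParams(alpha=cfg.alpha, walks_per_node=cfg.walks_per_node,
                        walk_length=cfg.walk_length, seed=seeds["walks"])
    corpus = sample_walks(P, params)
    return train_embedding(corpus, d=cfg.dim, window=cfg.window, epochs=cfg.epochs,
                           neg_samples=cfg.neg_samples, seed=seeds["embedding"])


def run_pipeline(m: ExpressionMatrix, cfg: RunConfig,
                 truth: np.ndarray | None = None) -> tuple[ClusterLabels, EvalReport | None]:
    """Full pipeline on a raw count matrix; scores against truth if given."""
    seeds = _stage_seeds(cfg.seed)
    mp = preprocess(m, hvg=cfg.hvg)
    if truth is not None and mp.n_cells != m.n_cells:
        # drop_zero removed cells: subset truth to the retained cells
        keep = [m.cell_ids.index(c) for c in mp.cell_ids]
        truth = np.asarray(truth)[keep]
    if cfg.method == "pca-kmeans":
        labels = pca_kmeans_baseline(mp, d=min(cfg.dim, mp.n_genes - 1, mp.n_cells - 1),
                                     K=cfg.K, seed=cfg.seed)
    else:
        emb = embed_cells(mp, cfg)
        labels = kmeans_cluster(emb, cfg.K, seed=seeds["kmeans"], n_init=cfg.n_init)
    report = score(labels.assignment, truth) if truth is not None else None
    return labels, report


def pca_kmeans_baseline(m: ExpressionMatrix, d: int, K: int, seed: int = 0,
                        n_init: int = 10) -> ClusterLabels:
    """Reference baseline: top-d PCs of the cell x gene matrix, then K-means."""
    if d < 1:
        raise ValueError("d must be >= 1")
    X = m.dense().T  # cells x genes
    if d > min(X.shape):
        raise ValueError(f"d={d} exceeds matrix rank bound {min(X.shape)}")
    seeds = _stage_seeds(seed)
    Z = PCA(n_components=d, random_state=seeds["embedding"]).fit_transform(X)
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seeds["kmeans"])
    return ClusterLabels(km.fit_predict(Z), list(m.cell_ids), K)


def paper_like_profile(genes_per_module: float = 10.0, n_modules: int = 10,
                       seed: int = 0, **overrides) -> SimulationConfig:
    """The reconstructed default simulation profile used in the sweeps.

    Modularity is controlled through ``genes_per_module`` (average number of
    co-expressed genes per cell type) and ``n_modules`` (number of embedded
    cell types); the remaining parameters are held fixed.  The gene count
    scales as ``n_modules * genes_per_module`` so every gene belongs to a
    module and modularity is governed purely by the two knobs; background
    noise then perturbs the whole matrix.
    """
    base = dict(
        n_genes=int(round(n_modules * genes_per_module)), n_cells=500,
        n_types=n_modules,
        mean_genes_per_type=genes_per_module,
        mean_cells_per_type=500 / n_modules,
        lambda_ct=5.0, lambda_cross=3.0, lambda_bg=1.0,
        rho_ct=0.3, rho_cross=0.15, rho_bg=0.17, p_cross=0.4,
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def modularity_sweep(settings: list[dict], methods: list[str], reps: int = 10,
                     seed: int = 0, run_overrides: dict | None = None) -> pd.DataFrame:
    """Simulate, cluster, and score across modularity settings.

    ``settings`` are keyword overrides for :func:`paper_like_profile`; each
    setting is replicated ``reps`` times with derived seeds.  Returns a tidy
    frame (setting, method, replicate, measure, value) that includes the
    normalised Barber modularity of each simulated replicate.  Per-run
    failures are recorded (value NaN, measure "error") and the sweep
    continues.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    run_overrides = run_overrides or {}
    ss = np.random.SeedSequence(seed)
    rows = []
    for si, setting in enumerate(settings):
        for rep in range(reps):
            rep_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            cfg = paper_like_profile(seed=rep_seed, **setting)
            ds = simulate(cfg)
            try:
                mod = barber_modularity(ds.counts, ds.cell_labels, ds.gene_modules)
                rows.append(dict(setting=si, method="_data", replicate=rep,
                                 measure="normalized_modularity", value=mod.normalized))
            except ValueError as exc:
                logger.warning("modularity failed (setting=%s rep=%s): %s", si, rep, exc)
                rows.append(dict(setting=si, method="_data", replicate=rep,
                                 measure="error", value=np.nan))
            for method in methods:
                rc = RunConfig(method=method, K=cfg.n_types, seed=rep_seed, **run_overrides)
                try:
                    _, report = run_pipeline(ds.counts, rc, truth=ds.cell_labels)
                except Exception as exc:  # noqa: BLE001 — sweep must survive one bad run
                    logger.warning("run failed (setting=%s method=%s rep=%s): %s",
                                   si, method, rep, exc)
                    rows.append(dict(setting=si, method=method, replicate=rep,
                                     measure="error", value=np.nan))
                    continue
                for measure, value in report.to_dict().items():
                    if measure in ("ari", "nmi", "ami", "acc", "f1"):
                        rows.append(dict(setting=si, method=method, replicate=rep,
                                         measure=measure, value=float(value)))
    return pd.DataFrame(rows)


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and 95% CI (mean +/- 1.96*SE) per (setting, method, measure)."""
    def agg(g):
        v = g["value"].dropna()
        se = v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0
        return pd.Series({"mean": v.mean(), "ci_low": v.mean() - 1.96 * se,
                          "ci_high": v.mean() + 1.96 * se, "n": len(v)})
    return (df.groupby(["setting", "method", "measure"])
              .apply(agg, include_groups=False).reset_index())
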