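"""Hypergraph construction, random-walk transition kernels, walk sampling.

A gene x cell expression matrix is read directly as the incidence matrix of
a hypergraph: cells are nodes, genes are hyperedges, and the membership
weight of cell ``v`` in gene ``e`` is the expression gamma_e(v).  Four
node-to-node transition kernels are provided:

``edvw``
    Edge-dependent vertex weights: the edge-to-node step is proportional to
    the within-edge expression, the node-to-edge step sees only edge
    membership (weighted by the global edge weight omega).
``diphw``
    Dual-importance preference walk: both steps are expression-weighted and
    the edge-to-node weights are raised to a preference exponent alpha,
    sharpening transitions towards highly expressing cells.
``comem`` / ``comem-diphw``
    Memory-integrated walks: consecutive edge and node choices are
    modulated by gene (G_E) and cell (G_V) co-expression similarity, so the
    walker is steered among similar genes and cells.  ``comem`` uses
    expression-proportional inner selection probabilities; ``comem-diphw``
    uses the DIPHW forms with exponent alpha.

Walks are sampled from the collapsed node-to-node matrix; for node
sequences this is distributionally identical to alternating explicit
node/edge steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .coexpression import SimilarityNetwork
from .data import ExpressionMatrix

__all__ = [
    "IncidenceMatrix", "WalkParams", "TransitionMatrix", "WalkCorpus",
    "build_hypergraph", "diphw_transition", "edvw_transition",
    "comem_transition", "sample_walks",
]

#: refuse to build dense node-to-node matrices above this many cells
DEFAULT_CELL_CAP = 5000


@dataclass
class IncidenceMatrix:
    """Hypergraph incidence: |V| x |E|, entry (v, e) = gamma_e(v) >= 0."""

    I_H: np.ndarray
    edge_weights: np.ndarray
    node_ids: list[str]
    edge_ids: list[str]

    def __post_init__(self) -> None:
        self.I_H = np.asarray(self.I_H, dtype=float)
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        if self.I_H.ndim != 2:
            raise ValueError("incidence must be 2-D")
        if (self.I_H < 0).any():
            raise ValueError("incidence entries must be non-negative")
        if self.edge_weights.shape != (self.I_H.shape[1],):
            raise ValueError("one edge weight per hyperedge required")
        if (self.edge_weights <= 0).any():
            raise ValueError("edge weights must be positive")
        if (self.I_H.sum(axis=1) == 0).any() or (self.I_H.sum(axis=0) == 0).any():
            raise ValueError("incidence has an empty node or hyperedge; run drop_zero first")

    @property
    def n_nodes(self) -> int:
        return self.I_H.shape[0]

    @property
    def n_edges(self) -> int:
        return self.I_H.shape[1]


@dataclass
class WalkParams:
    """Walk-sampling parameters: exponent, walks per node, walk length."""

    alpha: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.walks_per_node < 1:
            raise ValueError("walks_per_node must be >= 1")
        if self.walk_length < 2:
            raise ValueError("walk_length must be >= 2")


@dataclass
class TransitionMatrix:
    """Row-stochastic |V| x |V| node-to-node transition matrix."""

    P: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if (self.P < 0).any():
            raise ValueError("transition probabilities must be non-negative")
        rows = self.P.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-8):
            bad = int(np.argmax(np.abs(rows - 1.0)))
            raise ValueError(f"row {bad} sums to {rows[bad]:.6g}, expected 1")


@dataclass
class WalkCorpus:
    """Sampled node paths; each path is a sequence of node indices."""

    paths: np.ndarray  # (n_walks, walk_length) int array
    node_ids: list[str] = field(default_factory=list)

    def as_sentences(self) -> list[list[str]]:
        return [[self.node_ids[i] for i in path] for path in self.paths]


def build_hypergraph(m: ExpressionMatrix, edge_weighting: str = "uniform",
                     edge_weights: np.ndarray | None = None) -> IncidenceMatrix:
    """Interpret a gene x cell matrix as a cell-node / gene-edge hypergraph.

    The incidence is the transpose of the expression matrix.  Under uniform
    weighting every hyperedge has omega = 1; ``edge_weighting="custom"``
    takes per-gene weights from ``edge_weights``.
    """
    X = m.dense()
    if (X.sum(axis=1) == 0).any() or (X.sum(axis=0) == 0).any():
        raise ValueError("matrix has zero-sum rows or columns; run drop_zero first")
    if edge_weighting == "uniform":
        omega = np.ones(m.n_genes)
    elif edge_weighting == "custom":
        if edge_weights is None:
            raise ValueError("custom weighting requires edge_weights")
        omega = np.asarray(edge_weights, dtype=float)
    else:
        raise ValueError("edge_weighting must be 'uniform' or 'custom'")
    return IncidenceMatrix(X.T.copy(), omega, list(m.cell_ids), list(m.gene_ids))


def _row_normalize(W: np.ndarray, what: str) -> np.ndarray:
    s = W.sum(axis=1, keepdims=True)
    if (s == 0).any():
        bad = int(np.flatnonzero(s.ravel() == 0)[0])
        raise ValueError(f"{what}: row {bad} has zero total weight")
    return W / s


def _powered(I: np.ndarray, alpha: float) -> np.ndarray:
    """gamma^alpha with 0^0 := 0 so the hyperedge support is preserved."""
    if alpha == 1.0:
        return I
    out = np.zeros_like(I)
    nz = I > 0
    out[nz] = I[nz] ** alpha
    return out


def diphw_transition(h: IncidenceMatrix, alpha: float = 1.0) -> TransitionMatrix:
    """Dual-importance preference walk kernel.

    P = D_{E|V}^{-1} W_{E|V}  D_{V|E}^{-1} W_{V|E} with
    W_{E|V}(v, e) = omega(e) * gamma_e(v) and W_{V|E}(e, v) = gamma_e(v)^alpha.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    P_ev = _row_normalize(h.I_H * h.edge_weights[None, :], "node-to-edge")
    W_ve = _powered(h.I_H, alpha) if alpha > 0 else (h.I_H > 0).astype(float)
    P_ve = _row_normalize(W_ve.T, "edge-to-node")
    return TransitionMatrix(P_ev @ P_ve, list(h.node_ids))


def edvw_transition(h: IncidenceMatrix) -> TransitionMatrix:
    """Edge-dependent vertex-weights baseline kernel.

    The node-to-edge step is membership-based (omega-weighted indicator);
    the edge-to-node step is expression-proportional.
    """
    member = (h.I_H > 0).astype(float)
    P_ev = _row_normalize(member * h.edge_weights[None, :], "node-to-edge")
    P_ve = _row_normalize(h.I_H.T, "edge-to-node")
    return TransitionMatrix(P_ev @ P_ve, list(h.node_ids))


def comem_transition(
    h: IncidenceMatrix,
    g_v: SimilarityNetwork,
    g_e: SimilarityNetwork,
    mode: str = "comem",
    alpha: float = 1.0,
    similarity_floor: float = 0.0,
) -> TransitionMatrix:
    """Memory-integrated walk kernel (CoMem / CoMem-DIPHW).

    Implements

        P(v1 -> v2)  ∝  sum_{e1, e2}  P_{V|E}(v1 | e1)
                        * P_{E2|V,E1}(e2 | v1, e1)
                        * P_{V_{t+1}|E,V_t}(v2 | e2, v1)

    where the edge continuation re-weights P(e2 | v1) by the edge
    similarity G_E(e1, e2) and the node continuation re-weights P(v2 | e2)
    by the node similarity G_V(v1, v2).  In mode ``comem`` the inner
    selection probabilities are expression-proportional; in
    ``comem-diphw`` they are the DIPHW forms with exponent ``alpha``.

    ``similarity_floor`` > 0 adds a constant to all off-diagonal
    similarities, guaranteeing every node retains transition mass; the
    default 0 errors loudly on nodes similar to nothing they can reach.
    """
    if mode not in ("comem", "comem-diphw"):
        raise ValueError("mode must be 'comem' or 'comem-diphw'")
    V, E = h.n_nodes, h.n_edges
    if g_v.values.shape != (V, V):
        raise ValueError(f"G_V must be {V}x{V}, got {g_v.values.shape}")
    if g_e.values.shape != (E, E):
        raise ValueError(f"G_E must be {E}x{E}, got {g_e.values.shape}")
    GV = g_v.values
    GE = g_e.values
    if (np.diag(GV) != 0).any() or (np.diag(GE) != 0).any():
        raise ValueError("similarity diagonals must be zero (non-lazy); apply non_lazy first")
    if similarity_floor > 0:
        GV = GV + similarity_floor
        GE = GE + similarity_floor
        np.fill_diagonal(GV, 0.0)
        np.fill_diagonal(GE, 0.0)

    if mode == "comem":
        P_ev = _row_normalize(h.I_H * h.edge_weights[None, :], "node-to-edge")  # V x E
        P_ve = _row_normalize(h.I_H.T, "edge-to-node")  # E x V
    else:
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        P_ev = _row_normalize(h.I_H * h.edge_weights[None, :], "node-to-edge")
        W_ve = _powered(h.I_H, alpha) if alpha > 0 else (h.I_H > 0).astype(float)
        P_ve = _row_normalize(W_ve.T, "edge-to-node")

    # d[v1, e1] = sum_e' G_E(e1, e') P(e' | v1)  — edge-memory normaliser
    D = P_ev @ GE  # V x E (G_E symmetric)
    W = P_ve.T  # W[v1, e1] = P(v1 | e1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(D > 0, W / D, 0.0)
    # s[v1, e2] = (sum_e1 C[v1, e1] G_E(e1, e2)) * P(e2 | v1)
    S = (C @ GE) * P_ev
    # q[v1, e2] = sum_w G_V(v1, w) P(w | e2)  — node-memory normaliser
    Q = GV @ P_ve.T  # V x E
    with np.errstate(divide="ignore", invalid="ignore"):
        SQ = np.where(Q > 0, S / Q, 0.0)
    P = (SQ @ P_ve) * GV
    mass = P.sum(axis=1)
    dangling = mass <= 0
    if dangling.any():
        if similarity_floor <= 0:
            bad = int(np.flatnonzero(dangling)[0])
            raise ValueError(
                f"node '{h.node_ids[bad]}' has zero transition mass (similar to nothing it "
                "can reach); pass similarity_floor > 0 to regularise")
        # nodes trapped by the non-lazy rule (e.g. cells expressing a single
        # gene) teleport uniformly to the other nodes
        row = np.full(V, 1.0 / max(V - 1, 1))
        for i in np.flatnonzero(dangling):
            P[i] = row
            P[i, i] = 0.0
        mass = P.sum(axis=1)
    return TransitionMatrix(P / mass[:, None], list(h.node_ids))


def sample_walks(P: TransitionMatrix, params: WalkParams,
                 cell_cap: int = DEFAULT_CELL_CAP) -> WalkCorpus:
    """Sample ``walks_per_node`` walks of ``walk_length`` from every node.

    Steps are drawn from the cumulative rows of P with inverse-CDF sampling;
    with a fixed seed the corpus is bit-reproducible.
    """
    V = P.P.shape[0]
    if V > cell_cap:
        raise ValueError(f"{V} nodes exceeds the dense-walk cap of {cell_cap}")
    rng = np.random.default_rng(params.seed)
    r, L = params.walks_per_node, params.walk_length
    prob, alias = _build_alias_tables(P.P)
    n_walks = r * V
    paths = np.empty((n_walks, L), dtype=np.int64)
    paths[:, 0] = np.tile(np.arange(V), r)
    for t in range(1, L):
        cur = paths[:, t - 1]
        j = rng.integers(0, V, size=n_walks)
        accept = rng.random(n_walks) < prob[cur, j]
        paths[:, t] = np.where(accept, j, alias[cur, j])
    return WalkCorpus(paths, list(P.node_ids))


def _build_alias_tables(P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row alias tables for O(1) categorical sampling (Vose's method)."""
    V = P.shape[0]
    prob = np.empty((V, V))
    alias = np.empty((V, V), dtype=np.int64)
    for i in range(V):
        p = P[i] * V
        pr = np.empty(V)
        al = np.arange(V)
        small = [j for j in range(V) if p[j] < 1.0]
        large = [j for j in range(V) if p[j] >= 1.0]
        p = p.copy()
        while small and large:
            s = small.pop()
            l = large.pop()
            pr[s] = p[s]
            al[s] = l
            p[l] = p[l] - (1.0 - p[s])
            (small if p[l] < 1.0 else large).append(l)
        for j in large:
            pr[j] = 1.0
        for j in small:
            pr[j] = 1.0
        prob[i] = pr
        alias[i] = al
    return prob, alias
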