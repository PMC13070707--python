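import numpy as np
import pytest

import hyperwalk as hw


@pytest.fixture
def toy_matrix():
    """4-gene x 4-cell matrix with two clean gene/cell modules."""
    X = np.array([
        [5, 4, 0, 0],
        [3, 6, 0, 0],
        [0, 0, 7, 2],
        [0, 0, 1, 8],
    ], dtype=float)
    return hw.ExpressionMatrix(X, [f"g{i}" for i in range(4)], [f"c{j}" for j in range(4)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_incidence(rng, n_nodes, n_edges, density=0.7, min_edges_per_node=1):
    """Random valid incidence matrix: no empty node or hyperedge.

    ``min_edges_per_node=2`` additionally guarantees every node can leave
    its current hyperedge, which the non-lazy memory walk requires.
    """
    while True:
        I = rng.random((n_nodes, n_edges)) * (rng.random((n_nodes, n_edges)) < density)
        I = np.round(I * 10, 3)
        if ((I.sum(axis=0) > 0).all()
                and ((I > 0).sum(axis=1) >= min_edges_per_node).all()):
            return I


def brute_force_diphw(I, omega, alpha):
    """Independent double-sum oracle for the dual-importance kernel."""
    V, E = I.shape
    P = np.zeros((V, V))
    for u in range(V):
        denom_u = sum(omega[e] * I[u, e] for e in range(E))
        for v in range(V):
            for e in range(E):
                if I[u, e] == 0:
                    continue
                members = [w for w in range(V) if I[w, e] > 0]
                denom_e = sum(I[w, e] ** alpha if alpha > 0 else 1.0 for w in members)
                gamma_v = (I[v, e] ** alpha if alpha > 0 else 1.0) if I[v, e] > 0 else 0.0
                P[u, v] += (omega[e] * I[u, e] / denom_u) * (gamma_v / denom_e)
    return P


def brute_force_edvw(I, omega):
    """Oracle for the membership-based baseline kernel."""
    V, E = I.shape
    P = np.zeros((V, V))
    for u in range(V):
        edges_u = [e for e in range(E) if I[u, e] > 0]
        denom_u = sum(omega[e] for e in edges_u)
        for e in edges_u:
            col = I[:, e]
            for v in range(V):
                P[u, v] += (omega[e] / denom_u) * (col[v] / col.sum())
    return P


def brute_force_comem(I, GV, GE, alpha=None):
    """Explicit triple-loop oracle for the memory-integrated kernel.

    ``alpha=None`` uses expression-proportional inner probabilities (comem);
    a float uses the preference forms (comem-diphw).
    """
    V, E = I.shape
    if alpha is None:
        W_ve = I.T  # edge-to-node weights
    elif alpha > 0:
        W_ve = np.zeros_like(I)
        W_ve[I > 0] = I[I > 0] ** alpha
        W_ve = W_ve.T
    else:
        W_ve = (I > 0).astype(float).T
    P_ve = W_ve / W_ve.sum(axis=1, keepdims=True)  # E x V: P(v | e)
    P_ev = I / I.sum(axis=1, keepdims=True)  # V x E: P(e | v)
    P = np.zeros((V, V))
    for v1 in range(V):
        for e1 in range(E):
            w1 = P_ve[e1, v1]
            if w1 == 0:
                continue
            d_edge = sum(GE[e1, ep] * P_ev[v1, ep] for ep in range(E))
            if d_edge == 0:
                continue
            for e2 in range(E):
                p_e2 = GE[e1, e2] * P_ev[v1, e2] / d_edge
                if p_e2 == 0:
                    continue
                d_node = sum(GV[v1, w] * P_ve[e2, w] for w in range(V))
                if d_node == 0:
                    continue
                for v2 in range(V):
                    P[v1, v2] += w1 * p_e2 * GV[v1, v2] * P_ve[e2, v2] / d_node
    mass = P.sum(axis=1, keepdims=True)
    return P / np.where(mass > 0, mass, 1.0)
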