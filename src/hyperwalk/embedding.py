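"""Skip-gram cell embeddings from walk corpora, and K-means clustering.

Walk paths are treated as sentences and fed to a skip-gram model with
negative sampling (word2vec-style: dynamic context window, unigram^0.75
negative-sampling distribution, linearly decaying learning rate).  The SGD
inner loop is numba-jitted and single-threaded, so training is fast and
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from sklearn.cluster import KMeans

from .hypergraph import WalkCorpus

__all__ = ["Embedding", "ClusterLabels", "train_embedding", "kmeans_cluster"]


@dataclass
class Embedding:
    vectors: np.ndarray  # (n_nodes, d)
    node_ids: list[str]

    @property
    def d(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ClusterLabels:
    """Cluster assignment per node; indices in 0..K-1."""

    assignment: np.ndarray
    node_ids: list[str]
    K: int


_SIGMOID_BINS = 4096
_SIGMOID_MAX = 8.0
_SIGMOID_TABLE = 1.0 / (1.0 + np.exp(-(np.arange(_SIGMOID_BINS) / _SIGMOID_BINS * 2
                                       - 1.0) * _SIGMOID_MAX))


@njit(cache=True, fastmath=True)
def _sg_train(paths, syn0, syn1, window, epochs, neg, neg_table, lr0, lr_min, seed,
              sigmoid_table):
    """Skip-gram negative-sampling SGD over walk paths.

    In-place update of input (syn0) and output (syn1) matrices.  Dynamic
    window and tabulated sigmoid, as in the reference word2vec
    implementation.
    """
    np.random.seed(seed)
    n_walks, L = paths.shape
    d = syn0.shape[1]
    n_bins = sigmoid_table.shape[0]
    total = epochs * n_walks * L
    done = 0
    grad_v = np.zeros(d, dtype=np.float32)
    for ep in range(epochs):
        for w in range(n_walks):
            for pos in range(L):
                lr = lr0 - (lr0 - lr_min) * (done / total)
                done += 1
                center = paths[w, pos]
                b = 1 + int(np.random.random() * window)
                lo = max(0, pos - b)
                hi = min(L, pos + b + 1)
                for cpos in range(lo, hi):
                    if cpos == pos:
                        continue
                    context = paths[w, cpos]
                    # predict `context` from `center`: update syn0[center]
                    v = syn0[center]
                    for j in range(d):
                        grad_v[j] = 0.0
                    for s in range(neg + 1):
                        if s == 0:
                            target = context
                            label = 1.0
                        else:
                            u = np.random.random()
                            target = neg_table[int(u * neg_table.shape[0])]
                            if target == context:
                                continue
                            label = 0.0
                        out = syn1[target]
                        dot = np.float32(0.0)
                        for j in range(d):
                            dot += v[j] * out[j]
                        if dot >= _SIGMOID_MAX:
                            p = 1.0
                        elif dot <= -_SIGMOID_MAX:
                            p = 0.0
                        else:
                            p = sigmoid_table[int((dot / _SIGMOID_MAX + 1.0)
                                                  / 2.0 * n_bins)]
                        g = np.float32(lr * (label - p))
                        for j in range(d):
                            grad_v[j] += g * out[j]
                            syn1[target, j] += g * v[j]
                    for j in range(d):
                        syn0[center, j] += grad_v[j]


def train_embedding(
    corpus: WalkCorpus,
    d: int = 64,
    window: int = 5,
    epochs: int = 10,
    neg_samples: int = 5,
    seed: int = 0,
    lr: float = 0.025,
) -> Embedding:
    """Train skip-gram node vectors on a walk corpus.

    Every node must appear in the corpus (all walks start from every node,
    so this only fails on a malformed corpus).  Deterministic for a fixed
    seed: the trainer is single-threaded.
    """
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    paths = np.ascontiguousarray(corpus.paths, dtype=np.int64)
    if paths.size == 0:
        raise ValueError("empty walk corpus")
    n_nodes = len(corpus.node_ids)
    counts = np.bincount(paths.ravel(), minlength=n_nodes).astype(float)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        names = [corpus.node_ids[i] for i in missing[:10]]
        raise ValueError(f"nodes absent from corpus (isolated?): {names}")
    # unigram^0.75 negative-sampling distribution
    p_neg = counts ** 0.75
    p_neg /= p_neg.sum()
    # word2vec-style sampling table: node i fills a share p_neg[i] of slots
    table_size = max(1 << 20, 64 * n_nodes)
    bounds = np.floor(np.cumsum(p_neg) * table_size).astype(np.int64)
    neg_table = np.zeros(table_size, dtype=np.int64)
    start = 0
    for i, stop in enumerate(bounds):
        neg_table[start:stop] = i
        start = stop
    neg_table[start:] = n_nodes - 1

    rng = np.random.default_rng(seed)
    # float32 weights, as in the reference word2vec implementation
    syn0 = ((rng.random((n_nodes, d)) - 0.5) / d).astype(np.float32)
    syn1 = np.zeros((n_nodes, d), dtype=np.float32)
    _sg_train(paths, syn0, syn1, window, epochs, neg_samples, neg_table,
              lr, 1e-4, seed % (2 ** 31), _SIGMOID_TABLE)
    return Embedding(syn0.astype(np.float64), list(corpus.node_ids))


def kmeans_cluster(e: Embedding, K: int, seed: int = 0, n_init: int = 10,
                   l2_normalize: bool = False) -> ClusterLabels:
    """K-means (k-means++ init, ``n_init`` restarts) on the embedding rows."""
    X = e.vectors
    if K > X.shape[0]:
        raise ValueError(f"K={K} exceeds the number of nodes {X.shape[0]}")
    if l2_normalize:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = X / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=K, n_init=n_init, random_state=seed % (2 ** 31))
    labels = km.fit_predict(X)
    return ClusterLabels(labels, list(e.node_ids), K)
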