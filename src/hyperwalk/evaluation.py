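"""External clustering evaluation: ARI, NMI, AMI, ACC, macro-F1.

All five measures are invariant to label permutation.  ACC and F1 first
match predicted clusters to true classes one-to-one with the Hungarian
algorithm (maximising the contingency-table trace); unmatched predicted
clusters contribute zero-F1 classes to the macro average.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    f1_score,
    normalized_mutual_info_score,
)

from .embedding import ClusterLabels

__all__ = ["EvalReport", "score"]


@dataclass
class EvalReport:
    ari: float
    nmi: float
    ami: float
    acc: float
    f1: float
    n_cells: int
    K_true: int
    K_pred: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_arrays(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pred, ClusterLabels) and isinstance(truth, ClusterLabels):
        if pred.node_ids != truth.node_ids:
            sym = set(pred.node_ids) ^ set(truth.node_ids)
            if sym:
                raise ValueError(f"node sets differ; symmetric difference: {sorted(sym)[:10]}")
            # same set, different order: align on truth's order
            idx = {n: i for i, n in enumerate(pred.node_ids)}
            order = [idx[n] for n in truth.node_ids]
            return np.asarray(pred.assignment)[order], np.asarray(truth.assignment)
        return np.asarray(pred.assignment), np.asarray(truth.assignment)
    p, t = np.asarray(pred), np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError("prediction and truth must cover the same nodes")
    return p, t


def _match_labels(pred: np.ndarray, truth: np.ndarray):
    """Optimal one-to-one cluster-to-class matching (Hungarian)."""
    p_vals, p_inv = np.unique(pred, return_inverse=True)
    t_vals, t_inv = np.unique(truth, return_inverse=True)
    C = np.zeros((len(p_vals), len(t_vals)), dtype=np.int64)
    np.add.at(C, (p_inv, t_inv), 1)
    n = max(C.shape)
    padded = np.zeros((n, n), dtype=np.int64)
    padded[: C.shape[0], : C.shape[1]] = C
    rows, cols = linear_sum_assignment(-padded)
    matched = padded[rows, cols].sum()
    # map predicted cluster -> matched truth class; unmatched clusters get
    # fresh labels outside the truth range so they count as zero-F1 classes
    mapping = {}
    extra = len(t_vals)
    for r, c in zip(rows, cols):
        if r < len(p_vals):
            mapping[r] = c if c < len(t_vals) else extra + r
    mapped = np.array([mapping[i] for i in p_inv])
    return matched, mapped, t_inv, len(t_vals)


def score(pred, truth) -> EvalReport:
    """Score a predicted clustering against ground truth.

    Accepts ``ClusterLabels`` pairs (aligned by node ID) or plain label
    arrays of equal length.
    """
    p, t = _as_arrays(pred, truth)
    n = len(t)
    matched, mapped_pred, t_codes, k_true = _match_labels(p, t)
    all_labels = np.unique(np.concatenate([mapped_pred, t_codes]))
    return EvalReport(
        ari=float(adjusted_rand_score(t, p)),
        nmi=float(normalized_mutual_info_score(t, p, average_method="arithmetic")),
        ami=float(adjusted_mutual_info_score(t, p, average_method="arithmetic")),
        acc=float(matched / n),
        f1=float(f1_score(t_codes, mapped_pred, labels=all_labels, average="macro",
                          zero_division=0)),
        n_cells=n,
        K_true=int(len(np.unique(t))),
        K_pred=int(len(np.unique(p))),
    )
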