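"""Adaptive positive sampling: filter KNN edges by soft-label similarity.

Two cells stay positives only if they are expression neighbors (KNN graph
A) AND their smoothed soft cluster labels agree: the soft-label adjacency
Â keeps pairs with cosine(g_i, g_j) ≥ λ, and the final adjacency is the
elementwise product A_final = A ⊙ Â.  Soft labels g are obtained by
averaging the two views' cluster-head outputs and smoothing over the
graph; by default the smoothing operator is the row-stochastic
random-walk normalization of (A + I), which keeps every g row on the
probability simplex (the unnormalized literal summation is available via
``normalize="none"``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_preprocess import CellGraph

__all__ = [
    "ClusterState",
    "smooth_soft_labels",
    "soft_label_adjacency",
    "final_adjacency",
    "pair_sampling_quality",
    "compute_cluster_state",
]


@dataclass
class ClusterState:
    g: np.ndarray
    hard_labels: np.ndarray
    A_hat: sp.csr_matrix
    A_final: sp.csr_matrix
    lam: float


def _adj(a) -> sp.csr_matrix:
    m = sp.csr_matrix(a)
    m.data = (m.data > 0).astype(np.float64)
    return m


def smooth_soft_labels(Y1: np.ndarray, Y2: np.ndarray, graph: CellGraph | sp.spmatrix,
                       normalize: str = "rw") -> np.ndarray:
    """g = Ã · (Y1 + Y2)/2 with Ã the row-normalized (A + I) (default)."""
    Y1 = np.asarray(Y1, dtype=np.float64)
    Y2 = np.asarray(Y2, dtype=np.float64)
    if Y1.shape != Y2.shape:
        raise ValueError("Y1 and Y2 must have the same shape")
    a = graph.adjacency if isinstance(graph, CellGraph) else _adj(graph)
    n = a.shape[0]
    if Y1.shape[0] != n:
        raise ValueError("soft labels and graph disagree on the number of cells")
    ymean = 0.5 * (Y1 + Y2)
    if normalize == "rw":
        a_self = a + sp.identity(n, format="csr")
        deg = np.asarray(a_self.sum(axis=1)).ravel()
        a_norm = sp.diags(1.0 / deg) @ a_self
        return np.asarray(a_norm @ ymean)
    if normalize == "none":
        return np.asarray(a @ ymean)
    raise ValueError(f"unknown normalization {normalize!r}")


def soft_label_adjacency(g: np.ndarray, lam: float,
                         candidate: sp.spmatrix | None = None) -> sp.csr_matrix:
    """Â_ij = 1 iff cosine(g_i, g_j) ≥ λ.

    With `candidate` given, Â is evaluated only on candidate edges (the
    result after intersecting with A is identical, at KNN-sparse cost).
    """
    g = np.asarray(g, dtype=np.float64)
    norms = np.linalg.norm(g, axis=1)
    if (norms == 0).any():
        raise ValueError("zero soft-label row; cannot compute cosine similarity")
    gn = g / norms[:, None]
    if candidate is None:
        sim = gn @ gn.T
        a_hat = (sim >= lam).astype(np.float64)
        return sp.csr_matrix(a_hat)
    cand = _adj(candidate).tocoo()
    sims = np.einsum("ij,ij->i", gn[cand.row], gn[cand.col])
    keep = sims >= lam
    return sp.csr_matrix(
        (np.ones(keep.sum()), (cand.row[keep], cand.col[keep])),
        shape=cand.shape,
    )


def final_adjacency(A: CellGraph | sp.spmatrix, A_hat: sp.spmatrix) -> sp.csr_matrix:
    """A_final = A ⊙ Â: positives must agree in expression and soft label."""
    a = A.adjacency if isinstance(A, CellGraph) else _adj(A)
    h = _adj(A_hat)
    if a.shape != h.shape:
        raise ValueError("A and A_hat shapes differ")
    out = a.multiply(h).tocsr()
    out.data = (out.data > 0).astype(np.float64)
    out.setdiag(0)
    out.eliminate_zeros()
    return out


def compute_cluster_state(Y1: np.ndarray, Y2: np.ndarray, graph: CellGraph,
                          lam: float = 0.9, normalize: str = "rw") -> ClusterState:
    """Full APS step: smooth labels → threshold similarities → intersect with A."""
    g = smooth_soft_labels(Y1, Y2, graph, normalize=normalize)
    a_hat = soft_label_adjacency(g, lam, candidate=graph.adjacency)
    a_hat = ((a_hat + a_hat.T) > 0).astype(np.float64)
    a_final = final_adjacency(graph, a_hat)
    return ClusterState(
        g=g,
        hard_labels=np.argmax(g, axis=1),
        A_hat=sp.csr_matrix(a_hat),
        A_final=a_final,
        lam=lam,
    )


def pair_sampling_quality(A_final: sp.spmatrix, A: sp.spmatrix,
                          true_labels: np.ndarray) -> tuple[float, float]:
    """PPV/NPV of the APS decision over KNN-candidate pairs.

    Universe: unordered pairs (i<j) with A_ij = 1.  Predicted positive:
    kept in A_final; predicted negative: dropped.  PPV = fraction of kept
    pairs with equal true labels; NPV = fraction of dropped pairs with
    unequal labels.  A denominator of zero yields NaN for that value.
    """
    a = _adj(A).toarray()
    af = _adj(A_final).toarray()
    labels = np.asarray(true_labels)
    if labels.shape[0] != a.shape[0]:
        raise ValueError("label vector length does not match adjacency")
    iu = np.triu_indices_from(a, k=1)
    cand = a[iu] > 0
    kept = af[iu][cand] > 0
    same = (labels[iu[0]] == labels[iu[1]])[cand]
    n_pos = kept.sum()
    n_neg = (~kept).sum()
    ppv = float(same[kept].mean()) if n_pos else float("nan")
    npv = float((~same[~kept]).mean()) if n_neg else float("nan")
    return ppv, npv
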