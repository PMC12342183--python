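"""Clustering agreement metrics: ARI, NMI, and assignment-matched accuracy."""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

__all__ = ["ari", "nmi", "acc"]


def _check(truth, pred):
    truth = np.asarray(truth).ravel()
    pred = np.asarray(pred).ravel()
    if truth.shape != pred.shape:
        raise ValueError(
            f"label vectors differ in length ({truth.size} vs {pred.size})"
        )
    if truth.size < 2:
        raise ValueError("need at least two samples")
    return truth, pred


def ari(truth, pred) -> float:
    """Adjusted Rand index (permutation-model expectation removed)."""
    truth, pred = _check(truth, pred)
    return float(adjusted_rand_score(truth, pred))


def nmi(truth, pred, average_method: str = "arithmetic") -> float:
    """Mutual information normalized by the mean of the two label entropies."""
    truth, pred = _check(truth, pred)
    return float(
        normalized_mutual_info_score(truth, pred, average_method=average_method)
    )


def acc(truth, pred) -> float:
    """Clustering accuracy under the best one-to-one cluster-id matching.

    Solved as a linear assignment on the contingency table; rectangular
    tables are handled by the rectangular assignment (unmatched ids
    contribute nothing), the standard deep-clustering convention.
    """
    truth, pred = _check(truth, pred)
    table = contingency_matrix(truth, pred)
    row, col = linear_sum_assignment(-table)
    return float(table[row, col].sum() / truth.size)
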