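"""Contrastive objectives: neighbor (instance-level), assignment (cluster-level),
and the cluster-balance entropy regularizer.

Instance level — for anchor z_i in one view, the positives are its own
augmentation in the other view plus every graph neighbor j (A_ij = 1) in
BOTH views; the denominator ranges over all cells in both views,
including the anchor's same-view self term (cosine 1), exactly as the
objective is defined.  Cluster level — the M columns of the cluster-head
output act as cluster representations; each column is contrasted against
its counterpart in the other view.  The entropy regularizer
L_reg = log M − H(Y) penalizes collapsing mass onto few clusters; by
default H is the entropy of per-view normalized cluster masses averaged
over the two views, so L_reg ∈ [0, log M] with 0 exactly at uniform
masses (`joint_view_entropy=True` instead normalizes the 2M masses of
both views jointly).

All functions accept numpy arrays or autodiff Tensors; given Tensors they
return a differentiable scalar Tensor, otherwise a float.  Ratios are
evaluated in log space with max-subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, concat, masked_logsumexp

__all__ = [
    "LossComponents",
    "neighbor_contrastive_loss",
    "cluster_contrastive_loss",
    "cluster_entropy_reg",
    "combine_losses",
]


@dataclass
class LossComponents:
    L_ins: float
    L_cls: float
    L_reg: float
    L_total: float
    tau: float
    alpha: float


def _as_tensor(x):
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def _dense01(a) -> np.ndarray:
    a = np.asarray(a.todense() if sp.issparse(a) else a, dtype=np.float64)
    return (a > 0).astype(np.float64)


def _row_normalize(x: Tensor, what: str) -> Tensor:
    sq = (x * x).sum(axis=1, keepdims=True)
    if (sq.data <= 0).any():
        raise ValueError(f"zero-norm row in {what}")
    return x / sq.sqrt()


def _maybe_float(value: Tensor, any_tensor: bool):
    return value if any_tensor else value.item()


def neighbor_contrastive_loss(z1, z2, adjacency, tau: float,
                              exclude_self: bool = False):
    """Instance-level neighbor contrastive loss, averaged over cells and views.

    `adjacency` is the (possibly APS-filtered) symmetric zero-diagonal
    cell graph defining which neighbors count as positives.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    z1, t1 = _as_tensor(z1)
    z2, t2 = _as_tensor(z2)
    a = _dense01(adjacency)
    n = z1.shape[0]
    if a.shape != (n, n):
        raise ValueError("adjacency shape does not match embeddings")
    if (np.diag(a) != 0).any():
        raise ValueError("adjacency must have zero diagonal")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    z1n = _row_normalize(z1, "z1")
    z2n = _row_normalize(z2, "z2")
    inv_tau = 1.0 / tau
    eye = np.eye(n)

    def one_direction(za: Tensor, zb: Tensor) -> Tensor:
        # exponents over [same-view | cross-view] candidates, shape n x 2n
        e_same = (za @ za.T) * inv_tau
        e_cross = (za @ zb.T) * inv_tau
        exponents = concat([e_same, e_cross], axis=1)
        denom_mask = np.ones((n, 2 * n))
        if exclude_self:
            denom_mask[:, :n] -= eye
        numer_mask = np.concatenate([a, a + eye], axis=1)
        li = masked_logsumexp(exponents, denom_mask, axis=1) - masked_logsumexp(
            exponents, numer_mask, axis=1
        )
        return li.sum()

    total = one_direction(z1n, z2n) + one_direction(z2n, z1n)
    return _maybe_float(total * (1.0 / (2 * n)), t1 or t2)


def cluster_contrastive_loss(Y1, Y2, tau: float, exclude_self: bool = False):
    """Cluster-level assignment contrastive loss over the M column vectors."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    Y1, t1 = _as_tensor(Y1)
    Y2, t2 = _as_tensor(Y2)
    m = Y1.shape[1]
    for name, y in (("Y1", Y1), ("Y2", Y2)):
        if (np.linalg.norm(y.data, axis=0) == 0).any():
            raise ValueError(
                f"{name} has an empty cluster column; the entropy regularizer "
                "L_reg should prevent this during training"
            )
    c1 = _row_normalize(Y1.T, "Y1 columns")
    c2 = _row_normalize(Y2.T, "Y2 columns")
    inv_tau = 1.0 / tau
    eye = np.eye(m)

    def one_direction(ca: Tensor, cb: Tensor) -> Tensor:
        e_same = (ca @ ca.T) * inv_tau
        e_cross = (ca @ cb.T) * inv_tau
        exponents = concat([e_same, e_cross], axis=1)
        denom_mask = np.ones((m, 2 * m))
        if exclude_self:
            denom_mask[:, :m] -= eye
        numer_mask = np.concatenate([np.zeros((m, m)), eye], axis=1)
        li = masked_logsumexp(exponents, denom_mask, axis=1) - masked_logsumexp(
            exponents, numer_mask, axis=1
        )
        return li.sum()

    total = one_direction(c1, c2) + one_direction(c2, c1)
    return _maybe_float(total * (1.0 / (2 * m)), t1 or t2)


def cluster_entropy_reg(Y1, Y2, joint_view_entropy: bool = False):
    """log M − H(Y) over normalized per-cluster mass.

    Default: entropy of each view's M normalized column masses, averaged
    over views (value in [0, log M], 0 iff uniform). With
    `joint_view_entropy` the 2M masses of both views are normalized
    together, as a single distribution.
    """
    Y1, t1 = _as_tensor(Y1)
    Y2, t2 = _as_tensor(Y2)
    if (Y1.data < 0).any() or (Y2.data < 0).any():
        raise ValueError("soft labels must be non-negative")
    if Y1.data.sum() == 0 or Y2.data.sum() == 0:
        raise ValueError("all-zero soft-label matrix")
    m = Y1.shape[1]
    mass1 = Y1.sum(axis=0)
    mass2 = Y2.sum(axis=0)

    def entropy(p: Tensor) -> Tensor:
        # 0·log 0 → 0: the tiny offset only touches exactly-zero masses
        return -(p * (p + 1e-300).log()).sum()

    if joint_view_entropy:
        total = mass1.sum() + mass2.sum()
        h = entropy(mass1 / total) + entropy(mass2 / total)
    else:
        h1 = entropy(mass1 / mass1.sum())
        h2 = entropy(mass2 / mass2.sum())
        h = (h1 + h2) * 0.5
    return _maybe_float(Tensor(np.log(m)) - h, t1 or t2)


def combine_losses(L_ins, L_cls_contrast, L_reg, alpha: float,
                   tau: float = 0.5) -> LossComponents:
    """Fold the regularizer into the cluster loss and mix instance vs cluster."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    f = lambda v: v.item() if isinstance(v, Tensor) else float(v)
    l_ins, l_clsc, l_reg = f(L_ins), f(L_cls_contrast), f(L_reg)
    l_cls = l_clsc + l_reg
    return LossComponents(
        L_ins=l_ins,
        L_cls=l_cls,
        L_reg=l_reg,
        L_total=alpha * l_ins + (1.0 - alpha) * l_cls,
        tau=tau,
        alpha=alpha,
    )
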