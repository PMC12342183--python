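"""Attribution of cluster assignments to genes, and marker-gene comparison.

Integrated gradients: for each cell, the pre-softmax cluster-head score
of its assigned cluster is attributed to the cell's genes by integrating
the gradient along the straight path from a baseline expression row
(zeros by default) to the observed row, holding the graph and every
other cell's expression fixed.  Because an L-layer encoder only mixes
information within L hops, the integral is evaluated on the cell's
L-hop induced subgraph, with all interpolation steps batched as one
block-diagonal forward pass.

Markers: a one-vs-rest Wilcoxon rank-sum test per gene with
Benjamini–Hochberg adjustment within each group, filtered at q ≤ fdr and
log fold-change ≥ min_lfc, ranked by fold-change.  This is the classic
scRNA-seq marker recipe and serves as the reference gene list against
which attribution rankings are compared by overlap counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .autodiff import Tensor
from .io_preprocess import CellGraph, CountMatrix
from .model import GraphContrastiveModel

__all__ = [
    "AttributionMatrix",
    "integrated_gradients",
    "rank_attributed_genes",
    "wilcoxon_markers",
    "overlap_heatmap_counts",
]


@dataclass
class AttributionMatrix:
    scores: np.ndarray          # M × p per-cluster mean attributions
    gene_ids: list[str]
    n_steps: int
    baseline_tag: str


def _hop_neighborhood(a: sp.csr_matrix, i: int, hops: int) -> np.ndarray:
    frontier = {i}
    seen = {i}
    for _ in range(hops):
        nxt = set()
        for node in frontier:
            nxt.update(a.indices[a.indptr[node] : a.indptr[node + 1]])
        frontier = nxt - seen
        seen |= frontier
    return np.array(sorted(seen))


def integrated_gradients(
    model: GraphContrastiveModel,
    x: np.ndarray | CountMatrix,
    graph: CellGraph,
    target_labels: np.ndarray,
    n_steps: int = 50,
    baseline: str = "zeros",
) -> np.ndarray:
    """Per-cell per-gene attributions of the assigned cluster's logit.

    Right Riemann-sum approximation of the path integral:
    IG_i = (x_i − b_i) ⊙ (1/T) Σ_{t=1..T} ∂F_c / ∂x_i at b + (t/T)(x − b).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be ≥ 1")
    xv = x.values if isinstance(x, CountMatrix) else np.asarray(x, dtype=np.float64)
    n, p = xv.shape
    labels = np.asarray(target_labels)
    if labels.shape[0] != n:
        raise ValueError("target_labels length does not match cells")
    if baseline == "zeros":
        base = np.zeros((n, p))
    elif baseline == "mean":
        base = np.broadcast_to(xv.mean(axis=0), (n, p)).copy()
    else:
        raise ValueError(f"unknown baseline {baseline!r}")

    a = graph.adjacency.tocsr()
    alphas = np.arange(1, n_steps + 1) / n_steps
    out = np.zeros((n, p))
    single_layer = model.cfg.n_layers == 1
    for i in range(n):
        if single_layer:
            grad_mean = _ig_grads_single_layer(model, xv, base[i], i, a,
                                               int(labels[i]), alphas)
        else:
            grad_mean = _ig_grads_generic(model, xv, base[i], i, a,
                                          int(labels[i]), alphas)
        out[i] = (xv[i] - base[i]) * grad_mean
    return out


def _ig_grads_single_layer(model, xv, base_i, i, a: sp.csr_matrix,
                           label: int, alphas: np.ndarray) -> np.ndarray:
    """All interpolation steps in one backward pass.

    With one attention layer only node i's encoder row feeds F_c(cell i),
    and that row attends over the fixed neighbors plus the interpolated
    self; the steps therefore batch as independent rows of a single
    star-attention forward.
    """
    from .autodiff import concat as _cat
    from .autodiff import layer_norm as _ln
    from .autodiff import softmax as _sm

    P = model.params
    cfg = model.cfg
    nb = a.indices[a.indptr[i] : a.indptr[i + 1]]
    path = base_i + alphas[:, None] * (xv[i] - base_i)
    xt = Tensor(path, requires_grad=True)
    h_i = xt @ P["w_in"] + P["b_in"]                       # T × d
    h_nb = Tensor(xv[nb]) @ P["w_in"] + P["b_in"]          # s × d (constant)
    q_all, k_self, v_self = (h_i @ P[w] for w in ("Q0", "K0", "V0"))
    k_nb, v_nb = (h_nb @ P[w] for w in ("K0", "V0"))
    dk = cfg.head_dim
    scale = 1.0 / np.sqrt(dk)
    s = nb.size
    heads = []
    for head in range(cfg.n_heads):
        sl = slice(head * dk, (head + 1) * dk)
        scores_nb = (q_all[:, sl] @ k_nb[:, sl].T) * scale
        scores_self = (q_all[:, sl] * k_self[:, sl]).sum(axis=1, keepdims=True) * scale
        w = _sm(_cat([scores_nb, scores_self], axis=1), axis=1)
        heads.append(w[:, :s] @ v_nb[:, sl] + w[:, s:] * v_self[:, sl])
    mixed = _cat(heads, axis=1) @ P["O0"]
    h1 = _ln(h_i + mixed, P["ln1_g0"], P["ln1_b0"])
    ffn = (h1 @ P["W1_0"] + P["b1_0"]).relu() @ P["W2_0"] + P["b2_0"]
    h_out = _ln(h1 + ffn, P["ln2_g0"], P["ln2_b0"])
    logits = model.cluster_logits(h_out)
    logits[:, label].sum().backward()
    return xt.grad.mean(axis=0)


def _ig_grads_generic(model, xv, base_i, i, a: sp.csr_matrix,
                      label: int, alphas: np.ndarray) -> np.ndarray:
    """Per-step induced-subgraph forward passes (any encoder depth)."""
    nodes = _hop_neighborhood(a, i, model.cfg.n_layers)
    pos = int(np.searchsorted(nodes, i))
    a_sub = a[nodes][:, nodes].toarray()
    grad_sum = np.zeros(xv.shape[1])
    for alpha in alphas:
        feats = xv[nodes].copy()
        feats[pos] = base_i + alpha * (xv[i] - base_i)
        xt = Tensor(feats, requires_grad=True)
        logits = model.cluster_logits(model.encoder(xt, a_sub, view=1))
        logits[(np.array([pos]), np.array([label]))].sum().backward()
        grad_sum += xt.grad[pos]
    return grad_sum / alphas.size


def rank_attributed_genes(
    att: np.ndarray,
    hard_labels: np.ndarray,
    gene_ids: list[str] | None = None,
    top_k: int = 200,
    n_steps: int = 50,
    baseline_tag: str = "zeros",
) -> tuple[AttributionMatrix, dict[int, list[str]]]:
    """Average attributions per predicted cluster; rank genes descending."""
    att = np.asarray(att, dtype=np.float64)
    labels = np.asarray(hard_labels)
    n, p = att.shape
    if labels.shape[0] != n:
        raise ValueError("labels length does not match attribution rows")
    gene_ids = list(gene_ids) if gene_ids is not None else [str(j) for j in range(p)]
    clusters = np.unique(labels)
    scores = np.zeros((clusters.size, p))
    lists: dict[int, list[str]] = {}
    for row, c in enumerate(clusters):
        members = labels == c
        if not members.any():
            warnings.warn(f"cluster {c} has no member cells")
            lists[int(c)] = []
            continue
        mean_att = att[members].mean(axis=0)
        scores[row] = mean_att
        order = np.argsort(-mean_att, kind="stable")[:top_k]
        lists[int(c)] = [gene_ids[j] for j in order]
    return (
        AttributionMatrix(scores=scores, gene_ids=gene_ids,
                          n_steps=n_steps, baseline_tag=baseline_tag),
        lists,
    )


def wilcoxon_markers(
    m: CountMatrix | np.ndarray,
    groups: np.ndarray,
    gene_ids: list[str] | None = None,
    fdr: float = 0.01,
    min_lfc: float = 1.0,
    top_k: int = 200,
) -> tuple[pd.DataFrame, dict[int, list[str]]]:
    """One-vs-rest rank-sum markers per group on log-normalized expression.

    Returns the full table (group, gene, lfc, pvalue, qvalue) and the
    per-group top_k gene lists after the q ≤ fdr and lfc ≥ min_lfc filter,
    ranked by descending log fold-change.
    """
    xv = m.values if isinstance(m, CountMatrix) else np.asarray(m, dtype=np.float64)
    if gene_ids is None:
        gene_ids = m.gene_ids if isinstance(m, CountMatrix) else [
            str(j) for j in range(xv.shape[1])
        ]
    groups = np.asarray(groups)
    if groups.shape[0] != xv.shape[0]:
        raise ValueError("groups length does not match cells")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise ValueError("need at least two groups")
    rows = []
    lists: dict[int, list[str]] = {}
    for gkey in uniq:
        members = groups == gkey
        if members.sum() < 2:
            warnings.warn(f"group {gkey} has fewer than 2 cells; skipped")
            continue
        xg, xr = xv[members], xv[~members]
        with np.errstate(all="ignore"):
            stat, pvals = mannwhitneyu(xg, xr, axis=0, alternative="two-sided")
        pvals = np.nan_to_num(pvals, nan=1.0)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        lfc = xg.mean(axis=0) - xr.mean(axis=0)
        frame = pd.DataFrame(
            {"group": gkey, "gene": gene_ids, "lfc": lfc,
             "pvalue": pvals, "qvalue": qvals}
        )
        rows.append(frame)
        surviving = frame[(frame.qvalue <= fdr) & (frame.lfc >= min_lfc)]
        surviving = surviving.sort_values("lfc", ascending=False, kind="stable")
        lists[int(gkey) if np.issubdtype(uniq.dtype, np.integer) else gkey] = (
            surviving.head(top_k)["gene"].tolist()
        )
    return pd.concat(rows, ignore_index=True), lists


def overlap_heatmap_counts(
    ig_lists: dict, deg_lists: dict
) -> pd.DataFrame:
    """Entry (predicted c, true t) = |ig_list_c ∩ deg_list_t|."""
    pred_keys = list(ig_lists)
    true_keys = list(deg_lists)
    counts = np.zeros((len(pred_keys), len(true_keys)), dtype=int)
    for ci, c in enumerate(pred_keys):
        sc = set(ig_lists[c])
        for ti, t in enumerate(true_keys):
            counts[ci, ti] = len(sc & set(deg_lists[t]))
    return pd.DataFrame(counts, index=pred_keys, columns=true_keys)
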