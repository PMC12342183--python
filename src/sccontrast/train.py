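"""End-to-end training: mini-batched contrastive optimization with APS refresh.

Each epoch shuffles cells into induced-subgraph mini-batches, draws fresh
masked views per batch, and minimizes L = α·L_ins + (1−α)·(L_cls + L_reg)
with Adam.  After a warm-up (default 20% of the epoch budget) during
which the raw KNN graph supplies the positives, the APS filter is
recomputed once per epoch from a mask-free full-graph forward pass and
its A_final replaces A in the instance loss.  Final cluster labels are
the row-wise argmax of the graph-smoothed soft labels g.

Contrastive denominators are batch-local: every similarity sum ranges
over the cells of the current mini-batch only, so full-batch and
mini-batch training coincide exactly when batch_size ≥ n.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.metrics import silhouette_score

from .aps import compute_cluster_state, smooth_soft_labels
from .augment import make_views
from .autodiff import Adam, Tensor
from .io_preprocess import CellGraph, CountMatrix, build_knn_graph
from .losses import (LossComponents, cluster_contrastive_loss,
                     cluster_entropy_reg, combine_losses,
                     neighbor_contrastive_loss)
from .model import EncoderConfig, GraphContrastiveModel

__all__ = [
    "TrainConfig",
    "LossConfig",
    "ApsConfig",
    "AugmentConfig",
    "FitResult",
    "default_batch_size",
    "make_batches",
    "fit",
    "select_n_clusters",
    "select_k",
]


def default_batch_size(n: int) -> int:
    """Size-dependent schedule: 64 below 1000 cells, 256 to 2000, 512 to 10000, 1024 above."""
    if n < 1000:
        return 64
    if n <= 2000:
        return 256
    if n <= 10_000:
        return 512
    return 1024


@dataclass
class TrainConfig:
    max_epochs: int = 500
    lr: float = 0.001
    batch_size: int | None = None  # None → size-dependent default
    seed: int = 0
    optimizer_tag: str = "adam"

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be ≥ 1")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size is not None and self.batch_size < 2:
            raise ValueError("batch_size must be ≥ 2")


@dataclass
class LossConfig:
    tau: float = 0.5
    alpha: float = 0.5
    exclude_self: bool = False
    joint_view_entropy: bool = False


@dataclass
class ApsConfig:
    lam: float = 0.9
    warmup_frac: float = 0.2
    refresh_every: int = 1
    normalize: str = "rw"
    enabled: bool = True


@dataclass
class AugmentConfig:
    mask_rate: float = 0.5
    rescale: bool = True


@dataclass
class FitResult:
    hard_labels: np.ndarray
    soft_labels: np.ndarray           # smoothed g, n × M
    embeddings: np.ndarray            # encoder h, n × d
    cluster_probs: np.ndarray         # raw cluster-head Y, n × M
    loss_history: list[LossComponents]
    model: GraphContrastiveModel
    graph: CellGraph
    A_final: sp.csr_matrix | None     # APS graph after the last refresh
    A_final_warmup: sp.csr_matrix | None  # APS graph at the first refresh
    config: dict
    seed: int

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cells = self.graph_cell_ids or [str(i) for i in range(len(self.hard_labels))]
        pd.DataFrame(
            {"cell_id": cells, "predicted_cluster": self.hard_labels}
        ).to_csv(outdir / "labels.csv", index=False)
        pd.DataFrame(self.soft_labels, index=cells).to_csv(outdir / "soft_labels.csv")
        pd.DataFrame(self.embeddings, index=cells).to_csv(outdir / "embeddings.csv")
        pd.DataFrame([asdict(c) for c in self.loss_history]).to_csv(
            outdir / "loss_history.csv", index=False
        )
        self.model.save(outdir / "checkpoint")
        (outdir / "manifest.json").write_text(
            json.dumps({"config": self.config, "seed": self.seed}, indent=2)
        )

    graph_cell_ids: list[str] | None = None


def make_batches(n_or_graph, batch_size: int, seed: int, epoch: int = 0):
    """Random permutation partitioned into chunks; a trailing chunk of size 1
    is merged into its predecessor so every batch has ≥ 2 cells."""
    if batch_size < 2:
        raise ValueError("batch_size must be ≥ 2")
    n = n_or_graph.n if isinstance(n_or_graph, CellGraph) else int(n_or_graph)
    ss = np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF,
                                spawn_key=(1, int(epoch)))
    rng = np.random.Generator(np.random.PCG64(ss))
    perm = rng.permutation(n)
    batches = [perm[i : i + batch_size] for i in range(0, n, batch_size)]
    if len(batches) > 1 and len(batches[-1]) < 2:
        batches[-2] = np.concatenate([batches[-2], batches[-1]])
        batches.pop()
    return batches


def _induced(a: sp.spmatrix, idx: np.ndarray) -> sp.csr_matrix:
    return sp.csr_matrix(a)[idx][:, idx]


def _check_finite(value: float, name: str):
    if not math.isfinite(value):
        raise FloatingPointError(f"non-finite loss component: {name} = {value}")


def fit(
    x: CountMatrix | np.ndarray,
    graph: CellGraph,
    enc_cfg: EncoderConfig,
    train_cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    aps_cfg: ApsConfig | None = None,
    aug_cfg: AugmentConfig | None = None,
) -> FitResult:
    """Train the dual-head graph contrastive model and assign clusters."""
    train_cfg = train_cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    aps_cfg = aps_cfg or ApsConfig()
    aug_cfg = aug_cfg or AugmentConfig()

    cell_ids = x.cell_ids if isinstance(x, CountMatrix) else None
    xv = x.values if isinstance(x, CountMatrix) else np.asarray(x, dtype=np.float64)
    n, p = xv.shape
    if enc_cfg.n_clusters > n:
        raise ValueError("n_clusters cannot exceed the number of cells")
    if graph.n != n:
        raise ValueError("graph and expression matrix disagree on cell count")

    batch_size = train_cfg.batch_size or default_batch_size(n)
    model = GraphContrastiveModel(enc_cfg, p, seed=train_cfg.seed)
    opt = Adam(model.parameters(), lr=train_cfg.lr)
    A = graph.adjacency
    a_positives = A  # graph used for instance-loss positives
    warmup_epochs = int(math.ceil(aps_cfg.warmup_frac * train_cfg.max_epochs))
    a_final = None
    a_final_warmup = None
    history: list[LossComponents] = []

    def full_forward():
        h = model.encoder(xv, A, view=1)
        return h, model.cluster_head(h)

    for epoch in range(train_cfg.max_epochs):
        if (
            aps_cfg.enabled
            and epoch >= warmup_epochs
            and (epoch - warmup_epochs) % aps_cfg.refresh_every == 0
        ):
            _, y_full = full_forward()
            state = compute_cluster_state(
                y_full.data, y_full.data, graph,
                lam=aps_cfg.lam, normalize=aps_cfg.normalize,
            )
            a_positives = state.A_final
            a_final = state.A_final
            if a_final_warmup is None:
                a_final_warmup = state.A_final

        batches = make_batches(n, batch_size, train_cfg.seed, epoch=epoch)
        epoch_parts = np.zeros(4)  # ins, cls_contrast, reg, total
        for bi, idx in enumerate(batches):
            views = make_views(
                xv[idx], aug_cfg.mask_rate,
                seed=train_cfg.seed, epoch=epoch * len(batches) + bi,
                rescale=aug_cfg.rescale,
            )
            a_batch_attn = _induced(A, idx)           # attention neighborhoods
            a_batch_pos = _induced(a_positives, idx)  # contrastive positives
            emb = model.forward_views(views.view1, views.view2, a_batch_attn)
            l_ins = neighbor_contrastive_loss(
                emb.z1, emb.z2, a_batch_pos, loss_cfg.tau, loss_cfg.exclude_self
            )
            l_clsc = cluster_contrastive_loss(
                emb.Y1, emb.Y2, loss_cfg.tau, loss_cfg.exclude_self
            )
            l_reg = cluster_entropy_reg(
                emb.Y1, emb.Y2, loss_cfg.joint_view_entropy
            )
            total = loss_cfg.alpha * l_ins + (1.0 - loss_cfg.alpha) * (l_clsc + l_reg)
            for name, t in (
                ("L_ins", l_ins), ("L_cls_contrast", l_clsc),
                ("L_reg", l_reg), ("L_total", total),
            ):
                _check_finite(t.item(), name)
            opt.zero_grad()
            total.backward()
            opt.step()
            epoch_parts += [l_ins.item(), l_clsc.item(), l_reg.item(), total.item()]
        epoch_parts /= len(batches)
        history.append(
            combine_losses(epoch_parts[0], epoch_parts[1], epoch_parts[2],
                           alpha=loss_cfg.alpha, tau=loss_cfg.tau)
        )

    h_full, y_full = full_forward()
    g = smooth_soft_labels(y_full.data, y_full.data, graph,
                           normalize=aps_cfg.normalize)
    hard = np.argmax(g, axis=1)

    return FitResult(
        hard_labels=hard,
        soft_labels=g,
        embeddings=h_full.data,
        cluster_probs=y_full.data,
        loss_history=history,
        model=model,
        graph=graph,
        A_final=a_final,
        A_final_warmup=a_final_warmup,
        config={
            "encoder": asdict(enc_cfg),
            "train": asdict(train_cfg),
            "loss": asdict(loss_cfg),
            "aps": asdict(aps_cfg),
            "augment": asdict(aug_cfg),
        },
        seed=train_cfg.seed,
        graph_cell_ids=cell_ids,
    )


def select_n_clusters(
    x: CountMatrix | np.ndarray,
    graph: CellGraph,
    candidate_Ms: list[int],
    budget_epochs: int = 100,
    seed: int = 0,
    space: str = "h",
    **cfg_overrides,
) -> int:
    """Silhouette-based unsupervised choice of the cluster number.

    Trains a short-budget model per candidate M and scores the hard
    labels by mean silhouette (Euclidean) in the chosen representation
    space (encoder h by default, or z / g); ties and degenerate
    single-cluster outcomes prefer the smaller M.
    """
    if not candidate_Ms:
        raise ValueError("candidate list must be non-empty")
    n = x.n_cells if isinstance(x, CountMatrix) else x.shape[0]
    best_m, best_score = None, -np.inf
    for m in sorted(candidate_Ms):
        if m < 2:
            raise ValueError("candidate cluster numbers must be ≥ 2")
        if m > n:
            import warnings

            warnings.warn(f"skipping candidate M={m} > n={n}")
            continue
        res = fit(
            x, graph,
            EncoderConfig(n_clusters=m, **cfg_overrides),
            TrainConfig(max_epochs=budget_epochs, seed=seed),
        )
        emb = {"h": res.embeddings, "g": res.soft_labels}.get(space)
        if emb is None:
            raise ValueError(f"unknown selection space {space!r}")
        if len(np.unique(res.hard_labels)) < 2:
            score = -1.0
        else:
            score = float(silhouette_score(emb, res.hard_labels, metric="euclidean"))
        if score > best_score:
            best_m, best_score = m, score
    if best_m is None:
        raise ValueError("no feasible candidate cluster number")
    return best_m


def select_k(
    x: CountMatrix,
    candidate_ks: list[int],
    n_clusters: int,
    budget_epochs: int = 100,
    seed: int = 0,
) -> int:
    """Unsupervised neighbor-count choice: k minimizing the final training loss."""
    if not candidate_ks:
        raise ValueError("candidate list must be non-empty")
    best_k, best_loss = None, np.inf
    for k in sorted(candidate_ks):
        graph = build_knn_graph(x, k=k)
        res = fit(
            x, graph,
            EncoderConfig(n_clusters=n_clusters),
            TrainConfig(max_epochs=budget_epochs, seed=seed),
        )
        final = res.loss_history[-1].L_total
        if final < best_loss:
            best_k, best_loss = k, final
    return best_k
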