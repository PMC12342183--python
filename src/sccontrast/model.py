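"""Graph-transformer encoder with instance- and cluster-level projection heads.

The encoder is a stack (default depth 1) of multi-head graph attention
layers: per head, a cell attends over its graph neighborhood plus itself
with scaled dot-product weights softmax_j((Q h_i · K h_j)/√d_k); head
outputs are concatenated, linearly mixed, and passed through residual +
layer-norm, a 2d-wide ReLU feed-forward block, and a second residual +
layer-norm.  Because attention inputs are d-dimensional, a learned linear
projection maps the p-dimensional expression row to d before the stack.

Two heads sit on the encoder output h: an instance head (MLP d→d→q) whose
output z feeds the neighbor contrastive loss, and a cluster head (MLP
d→d→M with row softmax) whose output Y holds soft cluster labels.  The
two augmented views are encoded by structurally identical encoders which
share parameters by default (a Siamese pair); `tied_encoders=False`
instantiates an independent second copy.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .augment import AugmentedViews
from .autodiff import Tensor, concat, layer_norm, softmax
from .io_preprocess import CellGraph

__all__ = [
    "EncoderConfig",
    "DualEmbeddings",
    "GraphContrastiveModel",
    "graph_attention_layer",
    "encode",
]


@dataclass
class EncoderConfig:
    n_clusters: int
    n_layers: int = 1
    n_heads: int = 4
    embed_dim: int = 32
    instance_dim: int = 32
    tied_encoders: bool = True

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be ≥ 2")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.n_heads


@dataclass
class DualEmbeddings:
    """Per-view encoder outputs h, instance-head z, cluster-head Y (autodiff Tensors)."""

    h1: Tensor
    h2: Tensor
    z1: Tensor
    z2: Tensor
    Y1: Tensor
    Y2: Tensor


def _linear_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


def _attention_mask(adjacency, n: int) -> np.ndarray:
    """Dense neighborhood mask N_i ∪ {i}: adjacency plus self-loops.

    Self-loops live only inside attention; the contrastive neighborhoods
    keep the zero-diagonal adjacency.
    """
    a = np.asarray(adjacency.todense() if hasattr(adjacency, "todense") else adjacency,
                   dtype=np.float64)
    a = (a > 0).astype(np.float64)
    np.fill_diagonal(a, 1.0)
    return a


def graph_attention_layer(
    h: Tensor, mask: np.ndarray, params: dict, layer: int, cfg: EncoderConfig,
    prefix: str = ""
) -> Tensor:
    """One graph-transformer layer (attention → mix → residual/norm → FFN → residual/norm)."""
    hds, dk = cfg.n_heads, cfg.head_dim
    q = h @ params[f"{prefix}Q{layer}"]
    k = h @ params[f"{prefix}K{layer}"]
    v = h @ params[f"{prefix}V{layer}"]
    neg = Tensor(np.where(mask > 0, 0.0, -np.inf))
    outs = []
    scale = 1.0 / np.sqrt(dk)
    for head in range(hds):
        sl = slice(head * dk, (head + 1) * dk)
        scores = (q[:, sl] @ k[:, sl].T) * scale + neg
        attn = softmax(scores, axis=-1)
        outs.append(attn @ v[:, sl])
    mixed = concat(outs, axis=1) @ params[f"{prefix}O{layer}"]
    h1 = layer_norm(h + mixed, params[f"{prefix}ln1_g{layer}"],
                    params[f"{prefix}ln1_b{layer}"])
    ffn = (h1 @ params[f"{prefix}W1_{layer}"] + params[f"{prefix}b1_{layer}"]).relu()
    ffn = ffn @ params[f"{prefix}W2_{layer}"] + params[f"{prefix}b2_{layer}"]
    return layer_norm(h1 + ffn, params[f"{prefix}ln2_g{layer}"],
                      params[f"{prefix}ln2_b{layer}"])


class GraphContrastiveModel:
    """Parameter container + functional forward passes for the encoder and heads."""

    def __init__(self, cfg: EncoderConfig, input_dim: int, seed: int = 0):
        self.cfg = cfg
        self.input_dim = int(input_dim)
        self.params: dict[str, Tensor] = {}
        rng = np.random.Generator(np.random.PCG64(int(seed) & 0x7FFFFFFF))
        self._init_encoder(rng, prefix="")
        if not cfg.tied_encoders:
            self._init_encoder(rng, prefix="e2_")
        self._init_heads(rng)

    # -- initialization -------------------------------------------------------
    def _add(self, name: str, rng, fan_in: int, shape):
        self.params[name] = Tensor(_linear_init(rng, fan_in, shape),
                                   requires_grad=True)

    def _init_encoder(self, rng, prefix: str):
        d, p = self.cfg.embed_dim, self.input_dim
        self._add(f"{prefix}w_in", rng, p, (p, d))
        self._add(f"{prefix}b_in", rng, p, (d,))
        for l in range(self.cfg.n_layers):
            for name in ("Q", "K", "V", "O"):
                self._add(f"{prefix}{name}{l}", rng, d, (d, d))
            self.params[f"{prefix}ln1_g{l}"] = Tensor(np.ones(d), requires_grad=True)
            self.params[f"{prefix}ln1_b{l}"] = Tensor(np.zeros(d), requires_grad=True)
            self._add(f"{prefix}W1_{l}", rng, d, (d, 2 * d))
            self._add(f"{prefix}b1_{l}", rng, d, (2 * d,))
            self._add(f"{prefix}W2_{l}", rng, 2 * d, (2 * d, d))
            self._add(f"{prefix}b2_{l}", rng, 2 * d, (d,))
            self.params[f"{prefix}ln2_g{l}"] = Tensor(np.ones(d), requires_grad=True)
            self.params[f"{prefix}ln2_b{l}"] = Tensor(np.zeros(d), requires_grad=True)

    def _init_heads(self, rng):
        d, q, m = self.cfg.embed_dim, self.cfg.instance_dim, self.cfg.n_clusters
        self._add("ih_w1", rng, d, (d, d))
        self._add("ih_b1", rng, d, (d,))
        self._add("ih_w2", rng, d, (d, q))
        self._add("ih_b2", rng, d, (q,))
        self._add("ch_w1", rng, d, (d, d))
        self._add("ch_b1", rng, d, (d,))
        self._add("ch_w2", rng, d, (d, m))
        self._add("ch_b2", rng, d, (m,))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward passes -------------------------------------------------------
    def encoder(self, x, adjacency, view: int = 1) -> Tensor:
        """Encoder output h for one view; `adjacency` may be sparse or dense."""
        prefix = "" if (self.cfg.tied_encoders or view == 1) else "e2_"
        x = x if isinstance(x, Tensor) else Tensor(x)
        n = x.shape[0]
        mask = _attention_mask(adjacency, n)
        if mask.shape != (n, n):
            raise ValueError(
                f"graph has {mask.shape[0]} nodes but views have {n} cells"
            )
        h = x @ self.params[f"{prefix}w_in"] + self.params[f"{prefix}b_in"]
        for l in range(self.cfg.n_layers):
            h = graph_attention_layer(h, mask, self.params, l, self.cfg, prefix)
        return h

    def attention_weights(self, x, adjacency, layer: int = 0,
                          view: int = 1) -> np.ndarray:
        """Per-head attention weight matrices (H, n, n) at the given layer.

        Rows are softmax-normalized over each node's neighborhood plus
        itself; non-neighborhood entries are exactly zero.
        """
        prefix = "" if (self.cfg.tied_encoders or view == 1) else "e2_"
        x = x if isinstance(x, Tensor) else Tensor(x)
        n = x.shape[0]
        mask = _attention_mask(adjacency, n)
        h = x @ self.params[f"{prefix}w_in"] + self.params[f"{prefix}b_in"]
        for l in range(layer):
            h = graph_attention_layer(h, mask, self.params, l, self.cfg, prefix)
        dk = self.cfg.head_dim
        q = (h @ self.params[f"{prefix}Q{layer}"]).data
        k = (h @ self.params[f"{prefix}K{layer}"]).data
        neg = np.where(mask > 0, 0.0, -np.inf)
        weights = np.zeros((self.cfg.n_heads, n, n))
        for head in range(self.cfg.n_heads):
            sl = slice(head * dk, (head + 1) * dk)
            scores = q[:, sl] @ k[:, sl].T / np.sqrt(dk) + neg
            shift = scores.max(axis=1, keepdims=True)
            e = np.exp(scores - shift)
            weights[head] = e / e.sum(axis=1, keepdims=True)
        return weights

    def instance_head(self, h: Tensor) -> Tensor:
        z = (h @ self.params["ih_w1"] + self.params["ih_b1"]).relu()
        return z @ self.params["ih_w2"] + self.params["ih_b2"]

    def cluster_logits(self, h: Tensor) -> Tensor:
        y = (h @ self.params["ch_w1"] + self.params["ch_b1"]).relu()
        return y @ self.params["ch_w2"] + self.params["ch_b2"]

    def cluster_head(self, h: Tensor) -> Tensor:
        return softmax(self.cluster_logits(h), axis=-1)

    def forward_views(self, view1, view2, adjacency) -> DualEmbeddings:
        h1 = self.encoder(view1, adjacency, view=1)
        h2 = self.encoder(view2, adjacency, view=2)
        return DualEmbeddings(
            h1=h1, h2=h2,
            z1=self.instance_head(h1), z2=self.instance_head(h2),
            Y1=self.cluster_head(h1), Y2=self.cluster_head(h2),
        )

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"config": asdict(self.cfg), "input_dim": self.input_dim}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "GraphContrastiveModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(EncoderConfig(**meta["config"]), meta["input_dim"], seed=0)
        with np.load(path.with_suffix(".npz")) as arc:
            for k in model.params:
                model.params[k].data = arc[k].astype(np.float64)
        return model


def encode(views: AugmentedViews, graph: CellGraph, cfg: EncoderConfig,
           model: GraphContrastiveModel) -> DualEmbeddings:
    """Encode two augmented views over the (unperturbed) cell graph."""
    if views.view1.shape[0] != graph.n:
        raise ValueError("views and graph disagree on the number of cells")
    return model.forward_views(views.view1, views.view2, graph.adjacency)
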