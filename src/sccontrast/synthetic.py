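"""Cluster-structured synthetic scRNA-seq counts.

The generator follows the splatter-like skeleton: per-cell cluster drawn
uniformly; per-gene baseline mean, multiplied by 2^lfc on the cluster's
marker genes (marker sets are disjoint across clusters); a lognormal
per-cell library-size factor with a stated coefficient of variation;
negative-binomial sampling (Gamma–Poisson mixture, variance
μ + μ²/dispersion); and independent Bernoulli dropout zeroing.  It is a
testbed with planted, recoverable structure — not a fit to any real
dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_preprocess import CountMatrix

__all__ = ["SimConfig", "simulate_counts", "default_fixture"]


@dataclass
class SimConfig:
    n_cells: int = 400
    n_genes: int = 500
    n_clusters: int = 4
    markers_per_cluster: int = 25
    lfc: float = 2.0
    nb_dispersion: float = 2.0
    base_mean: float = 2.0
    dropout_rate: float = 0.3
    library_size_cv: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.markers_per_cluster * self.n_clusters > self.n_genes:
            raise ValueError("marker genes exceed total genes")
        if self.nb_dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("nb_dispersion and base_mean must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be ≥ 0")


def simulate_counts(cfg: SimConfig):
    """Returns (CountMatrix raw, truth labels, marker_map cluster→gene-id set)."""
    rng = np.random.Generator(np.random.PCG64(int(cfg.seed) & 0x7FFFFFFF))
    n, p, m = cfg.n_cells, cfg.n_genes, cfg.n_clusters
    truth = rng.integers(0, m, size=n)

    marker_map: dict[int, set[str]] = {}
    gene_ids = [f"gene_{j:04d}" for j in range(p)]
    means = np.full((m, p), cfg.base_mean)
    for c in range(m):
        idx = np.arange(c * cfg.markers_per_cluster, (c + 1) * cfg.markers_per_cluster)
        means[c, idx] *= 2.0 ** cfg.lfc
        marker_map[c] = {gene_ids[j] for j in idx}

    # lognormal library factor with unit mean and the requested CV
    if cfg.library_size_cv > 0:
        sigma2 = np.log1p(cfg.library_size_cv**2)
        lib = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
    else:
        lib = np.ones(n)

    mu = means[truth] * lib[:, None]
    # NB via Gamma–Poisson: shape r, mean mu → variance mu + mu^2/r
    r = cfg.nb_dispersion
    lam = rng.gamma(shape=r, scale=mu / r)
    counts = rng.poisson(lam).astype(np.float64)
    if cfg.dropout_rate > 0:
        counts *= rng.random((n, p)) >= cfg.dropout_rate

    cm = CountMatrix(
        counts,
        cell_ids=[f"cell_{i:04d}" for i in range(n)],
        gene_ids=gene_ids,
        layer_tag="raw",
    )
    return cm, truth, marker_map


def default_fixture(seed: int = 7):
    """Canonical small benchmark: 400 cells, 500 genes, 4 clusters,
    25 markers/cluster at log2 fold-change 2.5, 30% dropout."""
    return simulate_counts(
        SimConfig(
            n_cells=400,
            n_genes=500,
            n_clusters=4,
            markers_per_cluster=25,
            lfc=2.5,
            dropout_rate=0.3,
            seed=seed,
        )
    )
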