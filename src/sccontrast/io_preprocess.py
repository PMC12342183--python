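"""Count-matrix I/O, quality control, normalization, HVG selection, KNN graph.

The preprocessing pipeline is the standard scRNA-seq recipe: drop cells
expressing fewer than 5 genes and genes expressed in fewer than 5 cells
(evaluated jointly on the input matrix in a single pass), scale each cell
to the median library size and apply log1p, keep the 3000 genes with the
highest normalized dispersion, and connect each cell to its k nearest
neighbors under cosine distance, symmetrizing the edge set by union.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "CellGraph",
    "read_counts",
    "write_counts",
    "quality_control",
    "normalize_log",
    "select_hvg",
    "build_knn_graph",
]


@dataclass
class CountMatrix:
    """Cells × genes expression matrix with identifiers.

    ``layer_tag`` tracks the pipeline stage: ``raw`` integer counts,
    ``lognorm`` after median-library scaling + log1p, ``hvg`` after
    variable-gene subsetting.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    layer_tag: str = "raw"

    def __post_init__(self):
        self.values = np.asarray(
            self.values.toarray() if sp.issparse(self.values) else self.values,
            dtype=np.float64,
        )
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if (self.values < 0).any():
            raise ValueError("negative expression values")
        if self.layer_tag == "raw" and not np.allclose(
            self.values, np.round(self.values)
        ):
            raise ValueError("raw layer must contain integer counts")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class CellGraph:
    """Sparse symmetric binary adjacency over cells (cosine-KNN, union-symmetrized)."""

    adjacency: sp.csr_matrix
    k: int
    metric_tag: str = "cosine"

    def __post_init__(self):
        a = sp.csr_matrix(self.adjacency)
        a.data = np.ones_like(a.data)
        self.adjacency = a
        if (abs(a - a.T)).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValueError("adjacency must have zero diagonal")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.adjacency.todense(), dtype=np.float64)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find_companion(dirname: Path, names: list[str]) -> Path:
    for name in names:
        for cand in (dirname / name, dirname / (name + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(
        f"none of {names} found next to matrix in {dirname}"
    )


def read_counts(path: str | os.PathLike, format: str | None = None) -> CountMatrix:
    """Read a raw count matrix; cells are rows in memory regardless of format.

    Supported formats: ``csv``/``tsv`` (header row = gene ids, first column =
    cell ids), ``mtx_10x`` (Matrix Market genes × cells plus barcodes and
    features/genes files, transposed on read), ``h5ad``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().removesuffix(".gz")
        format = {
            ".csv": "csv", ".tsv": "tsv", ".txt": "tsv",
            ".mtx": "mtx_10x", ".h5ad": "h5ad",
        }.get(path.suffix.lower() if path.suffix != ".gz" else suffix, None)
        if path.is_dir():
            format = "mtx_10x"
        if format is None:
            raise ValueError(f"cannot infer format of {path}")
    if not path.exists():
        raise FileNotFoundError(f"input not found: {path}")

    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        with _open_maybe_gz(path) as fh:
            header = fh.readline().rstrip("\r\n").split(sep)
        gene_ids = header[1:]  # pandas mangles duplicate headers; keep originals
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CountMatrix(df.values, list(df.index), gene_ids, "raw")

    if format == "mtx_10x":
        if path.is_dir():
            mtx_path = _find_companion(path, ["matrix.mtx"])
        else:
            mtx_path = path
        dirname = mtx_path.parent
        with _open_maybe_gz(mtx_path, "rt") as fh:
            mat = scipy.io.mmread(fh)  # genes x cells on disk
        features = _find_companion(dirname, ["features.tsv", "genes.tsv"])
        barcodes = _find_companion(dirname, ["barcodes.tsv"])
        feat = pd.read_csv(features, sep="\t", header=None)
        # 10x features files carry (id, symbol, type); use the first column
        gene_ids = list(feat.iloc[:, 0].astype(str))
        cell_ids = list(
            pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].astype(str)
        )
        return CountMatrix(sp.csr_matrix(mat).T, cell_ids, gene_ids, "raw")

    if format == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.X
        return CountMatrix(x, list(adata.obs_names), list(adata.var_names), "raw")

    raise ValueError(f"unknown format {format!r}")


def write_counts(m: CountMatrix, path: str | os.PathLike, format: str = "csv") -> None:
    """Write a count matrix; inverse of :func:`read_counts` for each format."""
    path = Path(path)
    if format in ("csv", "tsv"):
        sep = "," if format == "csv" else "\t"
        df = m.to_dataframe()
        if m.layer_tag == "raw":
            df = df.astype(np.int64)
        df.to_csv(path, sep=sep)
    elif format == "mtx_10x":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(
            str(path / "matrix.mtx"), sp.coo_matrix(m.values.T.astype(np.int64))
        )
        pd.Series(m.gene_ids).to_csv(
            path / "features.tsv", sep="\t", header=False, index=False
        )
        pd.Series(m.cell_ids).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
    elif format == "h5ad":
        import anndata as ad

        adata = ad.AnnData(
            X=m.values,
            obs=pd.DataFrame(index=m.cell_ids),
            var=pd.DataFrame(index=m.gene_ids),
        )
        adata.write_h5ad(path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def quality_control(
    m: CountMatrix, min_genes_per_cell: int = 5, min_cells_per_gene: int = 5
) -> CountMatrix:
    """Drop low-coverage cells and rarely expressed genes in one joint pass.

    Both filters are evaluated on the input matrix, then applied together:
    a retained cell expresses ≥ `min_genes_per_cell` genes and a retained
    gene is expressed in ≥ `min_cells_per_gene` cells, both counted on the
    original matrix.
    """
    if m.layer_tag != "raw":
        raise ValueError("quality_control expects the raw layer")
    nz = m.values > 0
    keep_cells = nz.sum(axis=1) >= min_genes_per_cell
    keep_genes = nz.sum(axis=0) >= min_cells_per_gene
    if not keep_cells.any() or not keep_genes.any():
        raise ValueError(
            "quality control removed every cell or gene; lower the thresholds"
        )
    return CountMatrix(
        m.values[np.ix_(keep_cells, keep_genes)],
        [c for c, k in zip(m.cell_ids, keep_cells) if k],
        [g for g, k in zip(m.gene_ids, keep_genes) if k],
        "raw",
    )


def normalize_log(m: CountMatrix) -> CountMatrix:
    """Scale each cell to the median library size, then log1p."""
    if m.layer_tag != "raw":
        raise ValueError("normalize_log expects the raw layer")
    totals = m.values.sum(axis=1)
    if (totals == 0).any():
        bad = [m.cell_ids[i] for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"cells with zero total counts: {bad[:5]}")
    target = np.median(totals)
    scaled = m.values * (target / totals)[:, None]
    out = CountMatrix.__new__(CountMatrix)
    out.values = np.log1p(scaled)
    out.cell_ids = list(m.cell_ids)
    out.gene_ids = list(m.gene_ids)
    out.layer_tag = "lognorm"
    return out


def _normalized_dispersion(logx: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Mean-binned dispersion z-scores on log data (classic Seurat recipe).

    Moments are taken on the de-logged values; dispersion = var/mean is
    z-scored within equal-frequency mean bins (quantile bins avoid the
    singleton bins equal-width binning produces on small inputs).
    Zero-variance genes score −inf so they can never outrank a variable
    gene.
    """
    x = np.expm1(logx)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    # a z-score needs a populated bin: keep ≥ 10 genes per bin
    n_bins = max(1, min(n_bins, len(mean) // 10))
    quantiles = np.quantile(mean, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantiles, mean, side="right") - 1, 0, n_bins - 1)
    z = np.empty_like(disp)
    # floor each bin's spread at a fraction of the global spread so bins of
    # near-identical dispersions do not amplify noise into large z-scores
    sd_floor = 0.05 * disp.std()
    for b in np.unique(bins):
        members = bins == b
        mu, sd = disp[members].mean(), disp[members].std()
        sd = max(sd, sd_floor)
        z[members] = (disp[members] - mu) / sd if sd > 0 else 0.0
    z[var <= 1e-13 * np.maximum(mean, 1.0) ** 2] = -np.inf
    return z


def select_hvg(m: CountMatrix, n_top: int = 3000) -> CountMatrix:
    """Keep the `n_top` genes with highest normalized dispersion.

    Ranking follows the classic Seurat-flavor recipe on log data
    (mean-binned dispersion z-scores); the retained genes keep their
    input order. Ties break toward the lower gene index.
    """
    if m.layer_tag != "lognorm":
        raise ValueError("select_hvg expects the lognorm layer")
    if n_top < 1:
        raise ValueError("n_top must be ≥ 1")
    p = m.n_genes
    if n_top >= p:
        out = CountMatrix.__new__(CountMatrix)
        out.values = m.values.copy()
        out.cell_ids = list(m.cell_ids)
        out.gene_ids = list(m.gene_ids)
        out.layer_tag = "hvg"
        return out

    disp = _normalized_dispersion(m.values)
    # stable argsort on (-disp, index) → deterministic lowest-index tie-break
    order = np.argsort(-disp, kind="stable")[:n_top]
    keep = np.zeros(p, dtype=bool)
    keep[order] = True
    out = CountMatrix.__new__(CountMatrix)
    out.values = m.values[:, keep]
    out.cell_ids = list(m.cell_ids)
    out.gene_ids = [g for g, k in zip(m.gene_ids, keep) if k]
    out.layer_tag = "hvg"
    return out


def preprocess(
    m: CountMatrix,
    min_genes_per_cell: int = 5,
    min_cells_per_gene: int = 5,
    n_top_genes: int = 3000,
) -> CountMatrix:
    """QC → median-library log-normalization → HVG subsetting."""
    return select_hvg(
        normalize_log(quality_control(m, min_genes_per_cell, min_cells_per_gene)),
        n_top_genes,
    )


def build_knn_graph(m: CountMatrix, k: int = 15) -> CellGraph:
    """Cosine-KNN graph over cells, union-symmetrized, zero diagonal.

    Each cell sends directed edges to its k nearest other cells by cosine
    distance; ties break toward the lower cell index; A := A ∨ Aᵀ.
    """
    if m.layer_tag != "hvg":
        raise ValueError("build_knn_graph expects the hvg layer")
    x = m.values
    n = x.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 ≤ k < n (k={k}, n={n})")
    norms = np.linalg.norm(x, axis=1)
    if (norms == 0).any():
        bad = [m.cell_ids[i] for i in np.flatnonzero(norms == 0)]
        raise ValueError(f"zero-norm expression vector for cells: {bad[:5]}")
    xn = x / norms[:, None]
    sim = xn @ xn.T
    np.fill_diagonal(sim, -np.inf)  # no self edges
    # argsort on (-sim, index): stable sort gives lowest-index tie-break
    nbr = np.argsort(-sim, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    a = sp.csr_matrix(
        (np.ones(n * k), (rows, nbr.ravel())), shape=(n, n)
    )
    a = ((a + a.T) > 0).astype(np.float64)
    a.setdiag(0)
    a.eliminate_zeros()
    return CellGraph(adjacency=sp.csr_matrix(a), k=k)
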