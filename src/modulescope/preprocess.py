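"""Normalisation through PCA and graph clustering.

The pipeline is: library-size normalisation to a fixed target total,
log1p transform, highly-variable-gene selection by binned dispersion,
per-gene z-scoring of the HVGs, PCA by SVD, and Leiden clustering of an
exact k-nearest-neighbour graph built on the PCA scores.

Each transform overwrites its output layer, so re-running a step is
idempotent and never stacks transforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import svd as dense_svd
from sklearn.neighbors import NearestNeighbors

from .core_io import ExpressionMatrix, PCAResult
from .errors import DataError, ParameterError, StateError

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "normalize_total",
    "log1p_transform",
    "select_hvgs",
    "scale_genes",
    "run_pca",
    "cluster_leiden",
    "run_preprocess",
]


@dataclass
class PreprocessConfig:
    """Default preprocessing parameters.

    target_total: per-cell total after normalisation (transcripts per 10k).
    n_hvgs / n_pcs / knn_k / leiden_resolution follow common single-cell
    practice; the seed controls Leiden's refinement randomness.
    """

    target_total: float = 10_000.0
    n_hvgs: int = 2_000
    n_pcs: int = 30
    knn_k: int = 15
    leiden_resolution: float = 1.0
    min_counts: int = 0  # QC filters default to off
    min_genes: int = 0
    seed: int = 0
    batch_hook: object = None  # callable (Y, batch) -> Y', identity if None


def normalize_total(X: ExpressionMatrix, s: float = 10_000.0) -> ExpressionMatrix:
    """Scale each cell to a fixed total count s; adds layer "norm".

    Cells with zero total counts cannot be normalised and are dropped with a
    warning.  Per-cell totals are stored in ``per_cell_stats["total_counts"]``.
    """
    if s <= 0:
        raise ParameterError(f"target total s must be positive, got {s}")
    totals = np.asarray(X.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        n_drop = int((totals == 0).sum())
        logger.warning("dropping %d cells with zero total counts", n_drop)
        X = X.subset_cells(totals > 0)
        totals = totals[totals > 0]
    norm = sp.csr_matrix(X.counts, dtype=float)
    scale = s / totals
    norm = sp.diags(scale) @ norm
    X.layers["norm"] = sp.csr_matrix(norm)
    X.per_cell_stats["total_counts"] = totals
    return X


def log1p_transform(X: ExpressionMatrix) -> ExpressionMatrix:
    """Natural-log transform ln(1 + x) of the normalised layer; adds "log"."""
    if "norm" not in X.layers:
        raise StateError('layer "norm" missing: run normalize_total first')
    logged = sp.csr_matrix(X.layers["norm"], dtype=float, copy=True)
    logged.data = np.log1p(logged.data)
    X.layers["log"] = logged
    return X


def _log_layer_moments(X: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean and unbiased (n-1) variance of the log layer."""
    L = X.layers["log"]
    n = L.shape[0]
    mu = np.asarray(L.mean(axis=0)).ravel()
    sq = np.asarray(L.multiply(L).mean(axis=0)).ravel() if sp.issparse(L) else (np.asarray(L) ** 2).mean(axis=0)
    var = (sq - mu**2) * n / max(n - 1, 1)
    return mu, np.maximum(var, 0.0)


def select_hvgs(X: ExpressionMatrix, n_top: int = 2_000, n_bins: int = 20) -> np.ndarray:
    """Flag the n_top most variable genes by binned standardised dispersion.

    Genes are binned into ``n_bins`` equal-count bins by mean log expression;
    within each bin the log dispersion ln(sigma^2 / mu) is z-scored, and genes
    are ranked by that z-score.  Zero-variance genes are never flagged; ties
    break by lexicographic gene id.
    """
    if "log" not in X.layers:
        raise StateError('layer "log" missing: run log1p_transform first')
    p = X.n_genes
    mu, var = _log_layer_moments(X)
    X.per_gene_stats["mean"] = mu
    X.per_gene_stats["var"] = var

    positive = var > 0
    n_positive = int(positive.sum())
    if n_top > n_positive:
        logger.warning(
            "requested %d HVGs but only %d genes have positive variance", n_top, n_positive
        )
        n_top = n_positive
    dispersion = np.full(p, -np.inf)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion[positive] = np.log(var[positive] / np.maximum(mu[positive], 1e-12))

    # equal-count mean bins over genes with positive variance
    z = np.full(p, -np.inf)
    idx = np.flatnonzero(positive)
    order = idx[np.argsort(mu[idx], kind="stable")]
    bins = np.array_split(order, min(n_bins, len(order)))
    for b in bins:
        d = dispersion[b]
        sd = d.std()
        z[b] = (d - d.mean()) / sd if sd > 0 else 0.0

    rank_key = pd.DataFrame(
        {"z": -z, "disp": -dispersion, "gene": X.gene_ids}
    ).sort_values(["z", "disp", "gene"], kind="stable")
    flags = np.zeros(p, dtype=bool)
    flags[rank_key.index[:n_top]] = True
    flags &= positive
    X.per_gene_stats["hvg"] = flags
    return flags


def scale_genes(X: ExpressionMatrix, max_value: float | None = None) -> ExpressionMatrix:
    """Z-score HVG columns of the log layer; adds dense layer "scaled".

    Uses the unbiased (n-1) standard deviation.  Non-HVG columns are zero.
    """
    if "hvg" not in X.per_gene_stats:
        raise StateError("HVG flags missing: run select_hvgs first")
    if X.n_cells < 2:
        raise DataError("scaling requires at least 2 cells")
    hvg = X.per_gene_stats["hvg"].to_numpy()
    L = X.layer_dense("log")[:, hvg]
    mu = L.mean(axis=0)
    sd = L.std(axis=0, ddof=1)
    assert (sd > 0).all(), "zero-variance gene among HVGs"
    Z = (L - mu) / sd
    if max_value is not None:
        Z = np.clip(Z, -max_value, max_value)
    scaled = np.zeros((X.n_cells, X.n_genes))
    scaled[:, hvg] = Z
    X.layers["scaled"] = scaled
    return X


def run_pca(X: ExpressionMatrix, d: int = 30) -> PCAResult:
    """PCA of the scaled HVG matrix via SVD of Z.

    Equivalent to the eigen-decomposition of the covariance Sigma = Z'Z/(n-1):
    eigenvalues are s_k^2/(n-1) and scores are Y = ZV.  Sign convention: each
    loading column's largest-magnitude entry is positive.
    """
    if "scaled" not in X.layers:
        raise StateError('layer "scaled" missing: run scale_genes first')
    hvg = X.per_gene_stats["hvg"].to_numpy()
    Z = X.layer_dense("scaled")[:, hvg]
    n = Z.shape[0]
    U, svals, Vt = dense_svd(Z, full_matrices=False)
    rank = int((svals > svals[0] * 1e-12).sum()) if len(svals) else 0
    if d > rank:
        logger.warning("reducing n_pcs from %d to matrix rank %d", d, rank)
        d = rank
    eigenvalues = svals**2 / (n - 1)
    V = Vt[:d].T
    # deterministic sign: largest-|.| entry of each loading column positive
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(d)])
    flip[flip == 0] = 1.0
    V = V * flip
    Y = Z @ V
    return PCAResult(
        scores=Y,
        loadings=V,
        eigenvalues=eigenvalues[:d],
        variance_explained_fraction=float(eigenvalues[:d].sum() / eigenvalues.sum()),
        hvg_genes=X.gene_ids[hvg],
    )


def knn_graph(Y: np.ndarray, k: int) -> ig.Graph:
    """Exact symmetric (union) k-nearest-neighbour graph with unit weights."""
    n = Y.shape[0]
    if k >= n:
        raise ParameterError(f"knn_k={k} must be < number of cells {n}")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(Y)
    _, nbr = nn.kneighbors(Y)
    edges = set()
    for i in range(n):
        for j in nbr[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def cluster_leiden(
    pca: PCAResult, k: int = 15, resolution: float = 1.0, seed: int = 0
) -> pd.Series:
    """Leiden communities (RB-modularity) on the exact KNN graph of PCA scores.

    Labels are relabelled by descending cluster size starting at 0.
    """
    g = knn_graph(pca.scores, k)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership)
    order = pd.Series(labels).value_counts().index.to_numpy()
    remap = {old: new for new, old in enumerate(order)}
    return pd.Series([remap[x] for x in labels], name="cluster")


def run_preprocess(
    X: ExpressionMatrix, config: PreprocessConfig | None = None, batch=None
) -> tuple[ExpressionMatrix, PCAResult, pd.Series]:
    """Full preprocessing chain returning (X with layers, PCA, cluster labels)."""
    cfg = config or PreprocessConfig()
    if cfg.min_counts or cfg.min_genes:
        totals = np.asarray(X.counts.sum(axis=1)).ravel()
        genes_per_cell = np.asarray((X.counts > 0).sum(axis=1)).ravel()
        keep = (totals >= cfg.min_counts) & (genes_per_cell >= cfg.min_genes)
        X = X.subset_cells(keep)
        if batch is not None:
            batch = np.asarray(batch)[keep]
    X = normalize_total(X, cfg.target_total)
    X = log1p_transform(X)
    select_hvgs(X, cfg.n_hvgs)
    X = scale_genes(X)
    pca = run_pca(X, cfg.n_pcs)
    if cfg.batch_hook is not None and batch is not None:
        pca.scores = cfg.batch_hook(pca.scores, batch)
    clusters = cluster_leiden(pca, cfg.knn_k, cfg.leiden_resolution, cfg.seed)
    clusters.index = X.cell_ids
    return X, pca, clusters
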