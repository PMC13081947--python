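"""Weighted co-expression network construction and module detection.

The chain is: gene-gene correlation on metacells, soft-power selection by
scale-free topology fit, unsigned adjacency a_ij = |r_ij|^beta, topological
overlap (TOM), average-linkage clustering of the TOM dissimilarity, and
branch extraction into colour-labelled modules with a grey pool for
unassigned genes.

The unsigned TOM follows the standard definition: with the diagonal of the
adjacency zeroed, L_ij = sum_u a_iu a_uj and k_i = sum_u a_iu,

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),   TOM_ii = 1.

Tree cutting is realised as a static cut at a quantile of the merge-height
range followed by a kME-based rescue of grey genes, which reproduces the
adaptive-boundary behaviour deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "WGCNA_COLORS",
    "CoexpressionNetwork",
    "SoftPowerScan",
    "ModuleAssignment",
    "gene_correlation",
    "scan_soft_power",
    "adjacency",
    "topological_overlap",
    "cut_modules",
    "build_network",
]

# the conventional WGCNA module colour sequence, assigned by descending size
WGCNA_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]

GREY = "grey"
MAX_NETWORK_GENES = 5_000


@dataclass
class SoftPowerScan:
    table: pd.DataFrame  # per beta: signed R^2, mean/median connectivity
    chosen_beta: float
    rule: str


@dataclass
class ModuleAssignment:
    labels: pd.Series  # gene -> colour (incl. "grey")
    min_module_size: int
    merge_heights: np.ndarray | None = None

    def module_genes(self, include_grey: bool = False) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for color in self.labels.unique():
            if color == GREY and not include_grey:
                continue
            out[color] = self.labels.index[self.labels == color].tolist()
        return out

    @property
    def modules(self) -> list[str]:
        sizes = self.labels[self.labels != GREY].value_counts()
        return sizes.index.tolist()


@dataclass
class CoexpressionNetwork:
    genes: pd.Index
    corr: np.ndarray
    method: str
    beta: float
    adjacency: np.ndarray
    tom: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


def _bicor(M: np.ndarray) -> np.ndarray:
    """Midweight bicorrelation (biweight midcorrelation) between columns."""
    med = np.median(M, axis=0)
    mad = np.median(np.abs(M - med), axis=0)
    # fall back to Pearson-style deviations where MAD is zero
    mad = np.where(mad == 0, 1e-12, mad)
    u = (M - med) / (9.0 * mad)
    w = (1 - u**2) ** 2 * (np.abs(u) < 1)
    xw = (M - med) * w
    norm = np.sqrt((xw**2).sum(axis=0))
    norm = np.where(norm == 0, 1e-12, norm)
    xn = xw / norm
    return np.clip(xn.T @ xn, -1.0, 1.0)


def gene_correlation(M, genes: list[str] | None = None, method: str = "pearson") -> pd.DataFrame:
    """Symmetric gene-gene correlation across metacells with unit diagonal.

    Zero-variance genes are dropped with a warning.  ``M`` is a
    MetacellMatrix, DataFrame, or array (rows = metacells).
    """
    expr = M.expr if hasattr(M, "expr") else pd.DataFrame(M)
    if genes is not None:
        expr = expr[list(genes)]
    if expr.shape[0] < 3:
        raise DataError("need at least 3 metacells for correlations")
    sd = expr.std(axis=0, ddof=1)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance genes", int((sd == 0).sum()))
        expr = expr.loc[:, sd > 0]
    X = expr.to_numpy(dtype=float)
    if X.shape[1] == 1:
        return pd.DataFrame([[1.0]], index=expr.columns, columns=expr.columns)
    if method == "pearson":
        r = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        r = np.corrcoef(rankdata(X, axis=0), rowvar=False)
    elif method == "bicor":
        r = _bicor(X)
    else:
        raise ParameterError(f"unknown correlation method {method!r}")
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.columns, columns=expr.columns)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of log10(freq) ~ log10(mean k) over equal-width connectivity bins.

    Bins with no genes are dropped; fewer than 5 occupied bins means the
    degree distribution is too degenerate to judge and NaN is returned.
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return np.nan
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    keep = counts > 0
    if keep.sum() < 5:
        return np.nan
    kmean = np.array([k[which == b].mean() if counts[b] else np.nan for b in range(n_bins)])
    x = np.log10(kmean[keep])
    y = np.log10(counts[keep] / counts.sum())
    slope, _ = np.polyfit(x, y, 1)
    r2 = np.corrcoef(x, y)[0, 1] ** 2
    return float(-np.sign(slope) * r2)


def scan_soft_power(
    corr, betas=None, r2_target: float = 0.8
) -> SoftPowerScan:
    """Scan candidate soft powers and pick the smallest reaching the fit target.

    For each beta, connectivity k_i = sum_{j != i} |r_ij|^beta; the scale-free
    fit is the signed R^2 of the log-log degree-distribution regression.  The
    chosen beta is the smallest with signed R^2 >= ``r2_target``, else the
    argmax of signed R^2 (ties to the smaller beta).
    """
    betas = list(betas) if betas is not None else list(range(1, 21))
    if not betas:
        raise ParameterError("betas must be non-empty")
    R = np.abs(np.asarray(corr, dtype=float))
    if np.allclose(R, R.flat[0]):
        raise DataError("degenerate correlation matrix: all entries equal")
    np.fill_diagonal(R, 0.0)
    rows = []
    for beta in betas:
        k = (R**beta).sum(axis=0)
        rows.append(
            {
                "beta": beta,
                "signed_r2": _scale_free_fit(k),
                "mean_connectivity": float(k.mean()),
                "median_connectivity": float(np.median(k)),
            }
        )
    table = pd.DataFrame(rows)
    ok = table[table["signed_r2"] >= r2_target]
    if len(ok):
        chosen = float(ok["beta"].iloc[0])
        rule = f"smallest beta with signed R^2 >= {r2_target}"
    else:
        best = table["signed_r2"].fillna(-np.inf)
        chosen = float(table["beta"].iloc[int(best.argmax())])
        rule = "argmax signed R^2 (target not reached)"
    return SoftPowerScan(table=table, chosen_beta=chosen, rule=rule)


def adjacency(corr, beta: float) -> np.ndarray:
    """Unsigned adjacency a_ij = |r_ij|^beta with unit diagonal."""
    if beta <= 0:
        raise ParameterError(f"beta must be positive, got {beta}")
    a = np.abs(np.asarray(corr, dtype=float)) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Unsigned TOM of a symmetric adjacency with values in [0, 1]."""
    A = np.asarray(adj, dtype=float)
    if not np.allclose(A, A.T, atol=1e-10):
        raise ParameterError("adjacency must be symmetric")
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    L = A0 @ A0
    k = A0.sum(axis=0)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A0) / (kmin + 1.0 - A0)
    tom[~np.isfinite(tom)] = 0.0
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _color_labels(groups: dict[int, list[str]], all_genes: pd.Index) -> pd.Series:
    """Assign WGCNA colours by descending module size; leftovers grey."""
    labels = pd.Series(GREY, index=all_genes, dtype=object)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    for rank, (_, genes) in enumerate(ordered):
        color = WGCNA_COLORS[rank] if rank < len(WGCNA_COLORS) else f"module_{rank}"
        labels.loc[genes] = color
    return labels


def cut_modules(
    dissim,
    min_module_size: int = 30,
    cut_quantile: float = 0.99,
    kme_rescue_threshold: float = 0.30,
    expr=None,
) -> ModuleAssignment:
    """Average-linkage clustering of the TOM dissimilarity into colour modules.

    A static cut at ``cut_quantile`` of the maximum merge height (the WGCNA
    static-cut convention) yields candidate branches; branches of at least
    ``min_module_size`` genes become modules, everything else starts grey.
    Unstructured data merges at heights near the maximum, so a pure-noise
    dendrogram yields no branch below the cut and all genes stay grey.  If ``expr`` (metacells x genes) is supplied,
    grey genes are rescued into the module of their best eigengene correlation
    (kME) when that kME reaches ``kme_rescue_threshold``.
    """
    if min_module_size < 2:
        raise ParameterError("min_module_size must be >= 2")
    D = pd.DataFrame(dissim)
    genes = pd.Index(D.index)
    Dv = D.to_numpy(dtype=float)
    np.fill_diagonal(Dv, 0.0)
    Z = linkage(squareform(Dv, checks=False), method="average")
    heights = Z[:, 2]
    h_cut = cut_quantile * heights.max()
    flat = fcluster(Z, t=h_cut, criterion="distance")

    groups: dict[int, list[str]] = {}
    for cid in np.unique(flat):
        members = genes[flat == cid].tolist()
        if len(members) >= min_module_size:
            groups[int(cid)] = members
    if not groups:
        logger.warning("no branch reached min_module_size=%d: all genes grey", min_module_size)
    labels = _color_labels(groups, genes)

    if expr is not None and groups:
        labels = _kme_rescue(labels, expr, kme_rescue_threshold)
    return ModuleAssignment(labels=labels, min_module_size=min_module_size, merge_heights=heights)


def _kme_rescue(labels: pd.Series, expr, threshold: float) -> pd.Series:
    """Reassign grey genes to their best-kME module when kME >= threshold."""
    from .module_stats import compute_eigengenes, compute_kme  # circular at import time

    expr = expr.expr if hasattr(expr, "expr") else pd.DataFrame(expr)
    assignment = ModuleAssignment(labels=labels.copy(), min_module_size=2)
    if not assignment.modules:
        return labels
    eig = compute_eigengenes(expr, assignment)
    kme = compute_kme(expr, eig)
    grey_genes = labels.index[labels == GREY]
    sub = kme.loc[kme.index.intersection(grey_genes)]
    best = sub.idxmax(axis=1)
    best_val = sub.max(axis=1)
    rescued = best_val >= threshold
    out = labels.copy()
    out.loc[best.index[rescued]] = best[rescued]
    if rescued.any():
        logger.info("kME rescue reassigned %d grey genes", int(rescued.sum()))
    return out


def build_network(
    M,
    genes: list[str] | None = None,
    method: str = "pearson",
    beta: float | None = None,
    betas=None,
) -> tuple[CoexpressionNetwork, SoftPowerScan | None]:
    """Correlation -> (optional) soft-power scan -> adjacency -> TOM."""
    corr = gene_correlation(M, genes=genes, method=method)
    if corr.shape[0] > MAX_NETWORK_GENES:
        raise DataError(
            f"{corr.shape[0]} network genes exceeds the cap of {MAX_NETWORK_GENES}; "
            "restrict to HVGs or a user gene list"
        )
    scan = None
    if beta is None:
        scan = scan_soft_power(corr, betas)
        beta = scan.chosen_beta
    adj = adjacency(corr.to_numpy(), beta)
    tom = topological_overlap(adj)
    net = CoexpressionNetwork(
        genes=corr.index, corr=corr.to_numpy(), method=method, beta=beta,
        adjacency=adj, tom=tom,
    )
    return net, scan
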