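"""One-vs-rest Wilcoxon marker detection and its summary statistics.

Per cluster, every gene is tested with a two-sided Wilcoxon rank-sum
(normal approximation with tie and continuity correction) of in-cluster
versus all remaining cells on the log layer.  Benjamini-Hochberg
adjustment is applied across genes within each cluster comparison.
The table also carries the MA-plot quantities (log2 fold change M with
pseudocount eps, average expression A) and detection fractions.

Tau measures expression specificity across clusters: 0 for uniform
expression, 1 for expression confined to a single cluster.  Eigengene
inputs may be negative, so a per-feature shift to non-negative values is
applied before the formula (flagged via ``shifted``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .core_io import ExpressionMatrix
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "rank_genes_one_vs_rest",
    "detection_fraction",
    "top_deg_sets",
    "jaccard_matrix",
    "tau_scores",
    "deg_coherence",
    "classifier_validation",
    "wilcoxon_z",
]

LFC_EPS = 1e-6  # pseudocount in the log2 fold change


def wilcoxon_z(values: np.ndarray, in_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided rank-sum z and p per column of ``values``.

    Normal approximation with tie correction and a 0.5 continuity
    correction, matching the large-sample Mann-Whitney U test.
    """
    n = values.shape[0]
    n1 = int(in_mask.sum())
    n2 = n - n1
    if n1 < 1 or n2 < 1:
        raise DataError("both groups must be non-empty")
    ranks = rankdata(values, axis=0)
    r1 = ranks[in_mask].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    # tie correction on the variance
    tie_term = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(values[:, j], return_counts=True)
        t = counts[counts > 1]
        tie_term[j] = (t**3 - t).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sd = np.sqrt(var_u)
    diff = u - mean_u
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (diff - 0.5 * np.sign(diff)) / np.where(sd > 0, sd, 1.0), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def rank_genes_one_vs_rest(X: ExpressionMatrix, clusters) -> pd.DataFrame:
    """Per-(gene, cluster) Wilcoxon statistics with BH q-values and MA quantities."""
    clusters = pd.Series(np.asarray(clusters))
    labels = clusters.value_counts().sort_index().index
    if len(labels) < 2:
        raise DataError("need at least 2 clusters")
    L = X.layer_dense("log")
    # fold changes and MA averages are computed on normalised expression;
    # the rank test itself runs on the log layer
    if "norm" in X.layers:
        N = X.layer_dense("norm")
    else:
        N = np.maximum(np.expm1(L), 0.0)
    records = []
    for c in labels:
        in_mask = (clusters == c).to_numpy()
        if in_mask.sum() < 2 or (~in_mask).sum() < 2:
            logger.warning("cluster %r has <2 cells in a group; comparison skipped", c)
            continue
        z, p = wilcoxon_z(L, in_mask)
        q = multipletests(p, method="fdr_bh")[1]
        mean_in = N[in_mask].mean(axis=0)
        mean_out = N[~in_mask].mean(axis=0)
        lfc = np.log2((mean_in + LFC_EPS) / (mean_out + LFC_EPS))
        avg = 0.5 * (mean_in + mean_out)
        frac_in = (L[in_mask] > 0).mean(axis=0)
        frac_out = (L[~in_mask] > 0).mean(axis=0)
        records.append(
            pd.DataFrame(
                {
                    "gene": X.gene_ids,
                    "cluster": c,
                    "statistic": z,
                    "pvalue": p,
                    "qvalue": q,
                    "lfc": lfc,
                    "mean_in": mean_in,
                    "mean_out": mean_out,
                    "avg_expr": avg,
                    "detect_frac_in": frac_in,
                    "detect_frac_out": frac_out,
                }
            )
        )
    if not records:
        raise DataError("no cluster comparison could be performed")
    return pd.concat(records, ignore_index=True)


def detection_fraction(X: ExpressionMatrix, clusters, threshold: float = 0.0) -> pd.DataFrame:
    """Fraction of cells per cluster with log expression strictly above threshold."""
    clusters = pd.Series(np.asarray(clusters))
    L = X.layer_dense("log")
    out = {}
    for c in sorted(clusters.unique()):
        mask = (clusters == c).to_numpy()
        out[c] = (L[mask] > threshold).mean(axis=0)
    return pd.DataFrame(out, index=X.gene_ids)


def top_deg_sets(dea: pd.DataFrame, n: int = 100, require_positive_lfc: bool = True) -> dict:
    """Top-n marker genes per cluster, sorted by q (ties: |lfc| desc, gene id)."""
    if n <= 0:
        raise ParameterError(f"n must be positive, got {n}")
    if dea.empty:
        raise DataError("empty DEA table")
    sets = {}
    for c, sub in dea.groupby("cluster", sort=True):
        if require_positive_lfc:
            sub = sub[sub["lfc"] > 0]
        sub = sub.assign(_abs_lfc=-sub["lfc"].abs()).sort_values(
            ["qvalue", "_abs_lfc", "gene"], kind="stable"
        )
        sets[c] = sub["gene"].head(n).tolist()
    return sets


def jaccard_matrix(sets_a: dict, sets_b: dict) -> pd.DataFrame:
    """Pairwise Jaccard index |A n B| / |A u B|; 0 by convention when both empty."""
    rows = list(sets_a)
    cols = list(sets_b)
    out = np.zeros((len(rows), len(cols)))
    for i, a in enumerate(rows):
        sa = set(sets_a[a])
        for j, b in enumerate(cols):
            sb = set(sets_b[b])
            union = sa | sb
            if not union:
                logger.info("Jaccard(%r, %r): both sets empty, reporting 0", a, b)
                out[i, j] = 0.0
            else:
                out[i, j] = len(sa & sb) / len(union)
    return pd.DataFrame(out, index=rows, columns=cols)


def tau_from_means(means: np.ndarray, shift_negative: bool = False) -> float:
    """Tau = sum(1 - x_i/x_max)/(n-1) from a vector of cluster means."""
    x = np.asarray(means, dtype=float)
    n = len(x)
    if n < 2:
        raise ParameterError("Tau requires at least 2 clusters")
    if shift_negative:
        m = x.min()
        if m < 0:
            x = x - m
    xmax = x.max()
    if xmax <= 0:
        return np.nan
    return float((1.0 - x / xmax).sum() / (n - 1))


def tau_scores(values, clusters, shift_negative: bool = False) -> pd.DataFrame:
    """Per-feature Tau specificity over cluster means.

    ``values`` is a cells x features array/DataFrame (log expression or
    eigengenes).  With ``shift_negative`` each feature's cluster-mean vector
    is shifted so its minimum is zero before the formula (needed for signed
    eigengene inputs); the flag is recorded in the output.
    """
    df = pd.DataFrame(values)
    clusters = pd.Series(np.asarray(clusters), index=df.index)
    if clusters.nunique() < 2:
        raise ParameterError("Tau requires at least 2 clusters")
    cluster_means = df.groupby(clusters).mean()  # clusters x features
    taus = {
        feat: tau_from_means(cluster_means[feat].to_numpy(), shift_negative)
        for feat in df.columns
    }
    out = pd.DataFrame({"tau": pd.Series(taus)})
    out["shifted"] = shift_negative
    return out


def deg_coherence(X: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Pearson correlation of log-layer profiles among the given genes."""
    if len(genes) < 2:
        raise ParameterError("need at least 2 genes")
    if X.n_cells < 3:
        raise DataError("need at least 3 cells")
    idx = [X.gene_ids.get_loc(g) for g in genes]
    L = X.layer_dense("log")[:, idx]
    sd = L.std(axis=0)
    zero = sd == 0
    if zero.any():
        logger.warning("%d zero-variance genes: correlations reported as 0", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(L, rowvar=False)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=genes, columns=genes)


@dataclass
class ClassifierValidation:
    confusion: pd.DataFrame  # row-normalised, rows = true class
    per_class_accuracy: pd.Series
    genes_used: list[str]


def classifier_validation(
    train_X: ExpressionMatrix,
    train_labels,
    test_X: ExpressionMatrix,
    test_labels,
    deg_sets: dict,
    seed: int = 0,
    n_trees: int = 500,
) -> ClassifierValidation:
    """Random-Forest transfer test of marker genes onto an independent dataset.

    Trains on the train log layer restricted to the union of the DEG sets and
    predicts the test cells; genes absent from either dataset are imputed as 0.
    """
    train_labels = pd.Series(np.asarray(train_labels))
    test_labels = pd.Series(np.asarray(test_labels))
    missing_classes = set(test_labels.unique()) - set(train_labels.unique())
    if missing_classes:
        raise DataError(f"classes absent from training: {sorted(missing_classes)}")
    genes = sorted(set().union(*[set(v) for v in deg_sets.values()]))

    def build(X: ExpressionMatrix) -> np.ndarray:
        L = X.layer_dense("log")
        out = np.zeros((X.n_cells, len(genes)))
        n_missing = 0
        for j, g in enumerate(genes):
            if g in X.gene_ids:
                out[:, j] = L[:, X.gene_ids.get_loc(g)]
            else:
                n_missing += 1
        if n_missing:
            logger.warning("%d DEG genes missing from a dataset; imputed as 0", n_missing)
        return out

    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    clf.fit(build(train_X), train_labels)
    pred = clf.predict(build(test_X))

    classes = sorted(set(train_labels.unique()) | set(test_labels.unique()))
    conf = pd.DataFrame(0.0, index=classes, columns=classes)
    for t, p in zip(test_labels, pred):
        conf.loc[t, p] += 1
    row_sums = conf.sum(axis=1)
    conf_norm = conf.div(row_sums.replace(0, np.nan), axis=0).fillna(0.0)
    acc = pd.Series(
        {c: conf_norm.loc[c, c] for c in classes if row_sums[c] > 0}, name="accuracy"
    )
    return ClassifierValidation(conf_norm, acc, genes)
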