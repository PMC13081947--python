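"""Permutation-based module preservation between a reference and a test dataset.

For each non-grey module the observed statistics are:
  density      -- mean off-diagonal adjacency |r|^beta among the module's
                  genes in the *test* data (are they still densely connected?)
  connectivity -- correlation between each member gene's within-module
                  connectivity (kIM) in the reference and in the test data
                  (is the intramodular wiring pattern preserved?)

An empirical null is built from seeded random gene sets of equal size drawn
from the test network's genes; Z = (observed - null mean) / null sd per
statistic, and Z_summary is their arithmetic mean.  The conventional
interpretation: Z_summary > 10 strong, 2 < Z_summary <= 10 moderate,
Z_summary <= 2 not preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["PreservationReport", "module_preservation", "preservation_verdict"]

Z_STRONG = 10.0
Z_MODERATE = 2.0


@dataclass
class PreservationReport:
    table: pd.DataFrame  # per module: observed stats, Z scores, median rank
    n_permutations: int
    seed: int


def _expr_frame(M) -> pd.DataFrame:
    return M.expr if hasattr(M, "expr") else pd.DataFrame(M)


def _corr(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0)
    X = X + 0.0
    X[:, sd == 0] += 1e-12 * np.arange(X.shape[0])[:, None]  # avoid NaN columns
    r = np.corrcoef(X, rowvar=False)
    r[~np.isfinite(r)] = 0.0
    return r


def _stats_for_genes(ref_adj: np.ndarray, test_adj: np.ndarray) -> tuple[float, float]:
    """(density, connectivity) statistics for one gene set.

    ``ref_adj``/``test_adj`` are the adjacency submatrices of the same gene
    set in the two datasets.
    """
    m = ref_adj.shape[0]
    off = ~np.eye(m, dtype=bool)
    density = float(test_adj[off].mean())
    kim_ref = ref_adj.sum(axis=0) - np.diag(ref_adj)
    kim_test = test_adj.sum(axis=0) - np.diag(test_adj)
    if kim_ref.std() == 0 or kim_test.std() == 0:
        connectivity = 0.0
    else:
        connectivity = float(np.corrcoef(kim_ref, kim_test)[0, 1])
    return density, connectivity


def module_preservation(
    ref,
    test,
    modules,
    beta: float = 6.0,
    n_perm: int = 100,
    seed: int = 0,
    min_frac_shared: float = 0.8,
) -> PreservationReport:
    """Z_density / Z_connectivity / Z_summary and median rank per module."""
    if n_perm < 20:
        raise ParameterError("n_perm must be >= 20")
    ref_expr = _expr_frame(ref)
    test_expr = _expr_frame(test)
    shared = ref_expr.columns.intersection(test_expr.columns)
    module_genes = modules.module_genes() if hasattr(modules, "module_genes") else dict(modules)
    if not module_genes:
        raise DataError("no non-grey modules to evaluate")

    kept: dict[str, list[str]] = {}
    for name, genes in module_genes.items():
        present = [g for g in genes if g in shared]
        if genes and len(present) / len(genes) < min_frac_shared:
            logger.warning(
                "module %r: only %d/%d genes shared with the test data",
                name, len(present), len(genes),
            )
        if len(present) < 3:
            logger.warning("module %r has <3 genes in the test data; skipped", name)
            continue
        kept[name] = present
    if not kept:
        raise DataError("no module retains >=3 genes in the test data")

    # network genes: union of module genes plus all other shared genes
    net_genes = list(shared)
    gene_pos = {g: i for i, g in enumerate(net_genes)}
    ref_r = _corr(ref_expr[net_genes].to_numpy(dtype=float))
    test_r = _corr(test_expr[net_genes].to_numpy(dtype=float))
    ref_a = np.abs(ref_r) ** beta
    test_a = np.abs(test_r) ** beta

    rng = np.random.default_rng(seed)
    rows = []
    for name, genes in kept.items():
        idx = np.array([gene_pos[g] for g in genes])
        ref_sub = ref_a[np.ix_(idx, idx)]
        obs_d, obs_c = _stats_for_genes(ref_sub, test_a[np.ix_(idx, idx)])
        # null: the module keeps its reference-side identity while its genes
        # in the test network are replaced by a random set of equal size
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for t in range(n_perm):
            ridx = rng.choice(len(net_genes), size=len(idx), replace=False)
            null_d[t], null_c[t] = _stats_for_genes(
                ref_sub, test_a[np.ix_(ridx, ridx)]
            )

        def _z(obs, null):
            sd = null.std(ddof=1)
            if sd == 0:
                logger.warning("null sd = 0 for module %r; Z set to +inf", name)
                return np.inf if obs > null.mean() else -np.inf
            return (obs - null.mean()) / sd

        z_d = _z(obs_d, null_d)
        z_c = _z(obs_c, null_c)
        rows.append(
            {
                "module": name,
                "n_genes": len(idx),
                "observed_density": obs_d,
                "observed_connectivity": obs_c,
                "Z_density": z_d,
                "Z_connectivity": z_c,
                "Z_summary": (z_d + z_c) / 2.0,
            }
        )
    table = pd.DataFrame(rows).set_index("module")
    # median rank of the observed statistics across modules (1 = most preserved)
    rank_d = table["observed_density"].rank(ascending=False, method="min")
    rank_c = table["observed_connectivity"].rank(ascending=False, method="min")
    table["median_rank"] = (
        np.median(np.vstack([rank_d, rank_c]), axis=0).round().astype(int)
    )
    return PreservationReport(table=table, n_permutations=n_perm, seed=seed)


def preservation_verdict(report: PreservationReport) -> pd.Series:
    """Map Z_summary to {strong, moderate, none} at the conventional cut-offs.

    Boundaries: Z = 10 is moderate (strong requires Z > 10); Z = 2 is none.
    """
    def verdict(z: float) -> str:
        if z > Z_STRONG:
            return "strong"
        if z > Z_MODERATE:
            return "moderate"
        return "none"

    return report.table["Z_summary"].map(verdict).rename("verdict")
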