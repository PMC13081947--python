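"""Module eigengenes, kME hub analysis, module-level Tau and differential
module expression.

A module eigengene (ME) is the first principal component of the module's
column-standardised expression submatrix, rescaled to unit variance.  The
sign is fixed so the ME correlates non-negatively with the mean expression
of the module's genes, which makes downstream dot/track statistics
reproducible.  kME is the Pearson correlation of every gene with every ME,
computed on the single-cell log layer by default so hub ranking reflects
cell-level variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import svd as dense_svd
from statsmodels.stats.multitest import multipletests

from .dea import tau_scores, wilcoxon_z
from .errors import DataError, ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "EigengeneMatrix",
    "compute_eigengenes",
    "compute_kme",
    "hub_genes",
    "module_tau",
    "intermodule_correlation",
    "differential_module_expression",
]


@dataclass
class EigengeneMatrix:
    """Cells (or metacells) x modules eigengene scores, unit variance."""

    values: pd.DataFrame
    variance_explained: pd.Series
    space: str = "cells"
    sign_convention: str = "cor(ME, module mean expression) >= 0"

    @property
    def modules(self) -> list[str]:
        return list(self.values.columns)


def _as_expr_frame(X) -> pd.DataFrame:
    """Accept ExpressionMatrix (log layer), MetacellMatrix, or DataFrame."""
    if hasattr(X, "layers"):  # ExpressionMatrix
        return pd.DataFrame(
            X.layer_dense("log"), index=X.cell_ids, columns=X.gene_ids
        )
    if hasattr(X, "expr"):  # MetacellMatrix
        return X.expr
    return pd.DataFrame(X)


def compute_eigengenes(X, modules, space: str = "cells") -> EigengeneMatrix:
    """First-PC summary of each non-grey module, unit variance, sign-fixed."""
    expr = _as_expr_frame(X)
    module_genes = modules.module_genes() if hasattr(modules, "module_genes") else dict(modules)
    if not module_genes:
        raise DataError("no non-grey modules to summarise")
    cols, var_exp = {}, {}
    for name, genes in module_genes.items():
        present = [g for g in genes if g in expr.columns]
        if len(present) < 2:
            raise DataError(f"module {name!r} has {len(present)} genes in the matrix (<2)")
        sub = expr[present].to_numpy(dtype=float)
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        sd = np.where(sd == 0, 1.0, sd)
        Zs = (sub - mu) / sd
        U, svals, _ = dense_svd(Zs, full_matrices=False)
        me = U[:, 0] * svals[0]
        me_sd = me.std(ddof=1)
        me = me / (me_sd if me_sd > 0 else 1.0)
        mean_profile = Zs.mean(axis=1)
        if np.std(mean_profile) > 0 and np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        cols[name] = me
        var_exp[name] = float(svals[0] ** 2 / (svals**2).sum())
    values = pd.DataFrame(cols, index=expr.index)
    return EigengeneMatrix(
        values=values, variance_explained=pd.Series(var_exp), space=space
    )


def compute_kme(X, eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """Pearson correlation of every gene with every module eigengene."""
    expr = _as_expr_frame(X)
    ME = eigengenes.values
    if len(expr) != len(ME):
        raise DataError(
            f"cell mismatch: expression has {len(expr)} rows, eigengenes {len(ME)}"
        )
    Xv = expr.to_numpy(dtype=float)
    Mv = ME.to_numpy(dtype=float)
    Xc = Xv - Xv.mean(axis=0)
    Mc = Mv - Mv.mean(axis=0)
    xn = np.sqrt((Xc**2).sum(axis=0))
    mn = np.sqrt((Mc**2).sum(axis=0))
    zero = xn == 0
    if zero.any():
        logger.warning("%d zero-variance genes: kME reported as 0", int(zero.sum()))
    xn = np.where(zero, 1.0, xn)
    kme = (Xc / xn).T @ (Mc / mn)
    kme[zero] = 0.0
    kme = np.clip(kme, -1.0, 1.0)
    return pd.DataFrame(kme, index=expr.columns, columns=ME.columns)


def hub_genes(kme: pd.DataFrame, modules, n: int = 10) -> dict[str, list[str]]:
    """Top-n member genes per module by descending own-module kME (ties: gene id)."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    module_genes = modules.module_genes() if hasattr(modules, "module_genes") else dict(modules)
    out = {}
    for name, genes in module_genes.items():
        present = [g for g in genes if g in kme.index]
        ranked = (
            pd.DataFrame({"kme": kme.loc[present, name], "gene": present})
            .sort_values(["kme", "gene"], ascending=[False, True], kind="stable")
        )
        out[name] = ranked["gene"].head(n).tolist()
    return out


def module_tau(eigengenes: EigengeneMatrix, clusters) -> pd.DataFrame:
    """Tau specificity of each ME over clusters (min-shifted to non-negative)."""
    return tau_scores(eigengenes.values, clusters, shift_negative=True)


def intermodule_correlation(eigengenes: EigengeneMatrix) -> pd.DataFrame:
    """Pairwise Pearson correlation between MEs across cells."""
    ME = eigengenes.values
    if ME.shape[1] < 2:
        raise ParameterError("need at least 2 modules")
    r = np.corrcoef(ME.to_numpy(), rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=ME.columns, columns=ME.columns)


def differential_module_expression(eigengenes: EigengeneMatrix, groups) -> pd.DataFrame:
    """Two-sided Wilcoxon on ME values for every group pair, BH across modules."""
    ME = eigengenes.values
    groups = pd.Series(np.asarray(groups))
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ParameterError("need at least 2 groups")
    records = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ma = (groups == a).to_numpy()
            mb = (groups == b).to_numpy()
            if ma.sum() < 2 or mb.sum() < 2:
                logger.warning("group pair (%r, %r) degenerate; skipped", a, b)
                continue
            sub = ME.to_numpy()[ma | mb]
            in_mask = ma[ma | mb]
            z, p = wilcoxon_z(sub, in_mask)
            q = multipletests(p, method="fdr_bh")[1]
            mean_diff = ME.to_numpy()[ma].mean(axis=0) - ME.to_numpy()[mb].mean(axis=0)
            for j, m in enumerate(ME.columns):
                records.append(
                    {
                        "module": m, "group_a": a, "group_b": b,
                        "statistic": z[j], "pvalue": p[j], "qvalue": q[j],
                        "mean_difference": mean_diff[j],
                    }
                )
    if not records:
        raise DataError("no group pair could be tested")
    return pd.DataFrame(records)
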