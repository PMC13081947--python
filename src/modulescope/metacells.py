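"""KNN-based aggregation of similar cells into metacells.

Single-cell counts are too sparse for stable gene-gene correlations; a
metacell averages the log expression of a seed cell and its k-1 nearest
neighbours in PCA space, within one (cluster x condition) stratum.
Candidate metacells sharing more than ``max_shared`` cells with an
already accepted one are rejected, bounding redundancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .core_io import CellAnnotation, ExpressionMatrix, PCAResult
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = ["MetacellMatrix", "construct_metacells"]


@dataclass
class MetacellMatrix:
    """Metacells x genes expression with membership bookkeeping."""

    expr: pd.DataFrame  # metacells x genes
    membership: list[list[int]]  # per metacell, contributing cell indices
    group: pd.Series  # stratum label per metacell
    aggregation: str
    k: int

    @property
    def n_metacells(self) -> int:
        return self.expr.shape[0]

    @property
    def gene_ids(self) -> pd.Index:
        return self.expr.columns

    def values(self) -> np.ndarray:
        return self.expr.to_numpy()


def construct_metacells(
    X: ExpressionMatrix,
    pca: PCAResult,
    ann: CellAnnotation | pd.DataFrame,
    k: int = 25,
    max_shared: int = 10,
    target_per_stratum: int | None = None,
    aggregation: str = "mean",
    group_by: tuple[str, ...] = ("cluster", "condition"),
    seed: int = 0,
) -> MetacellMatrix:
    """Build metacells within each (cluster x condition) stratum.

    Seed cells are sampled without replacement by a seeded RNG; each seed's
    metacell is {seed} plus its k-1 nearest PCA-space neighbours in the same
    stratum.  ``target_per_stratum`` defaults to stratum_size // 3.
    Aggregation is the mean (default) or sum of the log layer.
    """
    if aggregation not in ("mean", "sum"):
        raise ParameterError(f"aggregation must be mean|sum, got {aggregation!r}")
    table = ann.table if isinstance(ann, CellAnnotation) else pd.DataFrame(ann)
    cols = [c for c in group_by if c in table.columns]
    if not cols:
        raise ParameterError(f"none of the grouping columns {group_by} present")
    strata = table[cols].astype(str).agg("|".join, axis=1).to_numpy()

    L = X.layer_dense("log")
    rng = np.random.default_rng(seed)
    rows, members, groups = [], [], []
    for stratum in sorted(pd.unique(strata)):
        idx = np.flatnonzero(strata == stratum)
        if len(idx) < k:
            logger.warning(
                "stratum %r has %d cells < k=%d; skipped", stratum, len(idx), k
            )
            continue
        target = target_per_stratum if target_per_stratum is not None else len(idx) // 3
        target = max(target, 1)
        nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(pca.scores[idx])
        _, nbr = nn.kneighbors(pca.scores[idx])  # includes self at position 0
        order = rng.permutation(len(idx))
        used: list[set] = []
        for local_seed in order:
            if len([g for g in groups if g == stratum]) >= target:
                break
            cand = set(int(idx[j]) for j in nbr[local_seed])
            if any(len(cand & prev) > max_shared for prev in used):
                continue
            used.append(cand)
            cells = sorted(cand)
            agg = L[cells].mean(axis=0) if aggregation == "mean" else L[cells].sum(axis=0)
            rows.append(agg)
            members.append(cells)
            groups.append(stratum)
    if not rows:
        raise ParameterError("no stratum was large enough to form metacells")
    expr = pd.DataFrame(
        np.vstack(rows),
        index=[f"metacell_{i}" for i in range(len(rows))],
        columns=X.gene_ids,
    )
    return MetacellMatrix(
        expr=expr,
        membership=members,
        group=pd.Series(groups, index=expr.index, name="group"),
        aggregation=aggregation,
        k=k,
    )
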