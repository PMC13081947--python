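"""DEG-module overlap, cross-condition module matching/consolidation, and
local hypergeometric gene-set enrichment.

Enrichment is an offline replacement for web enrichment services: each query
set is tested against user-supplied GMT terms with the upper-tail
hypergeometric probability of observing at least k overlapping genes, and
Benjamini-Hochberg adjustment across terms within the query set.

Cross-condition module similarity uses the Szymkiewicz-Simpson overlap
coefficient |A n B| / min(|A|, |B|); modules whose coefficient reaches a
threshold are linked, and connected components of that graph become
consolidated programs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_io import GeneSetCollection
from .dea import jaccard_matrix
from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentTable",
    "ProgramConsolidation",
    "hypergeometric_enrichment",
    "module_deg_jaccard",
    "overlap_coefficient",
    "overlap_coefficient_matrix",
    "consolidate_programs",
]


def _as_sets(obj) -> dict[str, list[str]]:
    if isinstance(obj, GeneSetCollection):
        return dict(obj.sets)
    if hasattr(obj, "module_genes"):
        return obj.module_genes()
    return dict(obj)


def hypergeometric_enrichment(sets, terms, universe: list[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of query sets against GMT terms.

    P = P(X >= k) with population M = |universe|, successes M_A = |term|,
    draws N = |query set|; terms are intersected with the universe first and
    empty intersections are skipped.  q-values are BH within each query set.
    """
    universe_set = set(universe)
    query_sets = _as_sets(sets)
    term_sets = _as_sets(terms)
    M = len(universe_set)
    records = []
    for qname, qgenes in query_sets.items():
        qs = set(qgenes) & universe_set
        if set(qgenes) - universe_set:
            logger.warning(
                "query %r: %d genes outside the universe ignored",
                qname, len(set(qgenes) - universe_set),
            )
        rows = []
        for tname, tgenes in term_sets.items():
            ts = set(tgenes) & universe_set
            if not ts:
                logger.info("term %r has no genes in the universe; skipped", tname)
                continue
            overlap = sorted(qs & ts)
            k = len(overlap)
            p = float(hypergeom.sf(k - 1, M, len(ts), len(qs))) if qs else 1.0
            rows.append(
                {
                    "set": qname, "term": tname, "overlap": k,
                    "set_size": len(qs), "term_size": len(ts), "universe_size": M,
                    "pvalue": min(p, 1.0), "overlap_genes": ",".join(overlap),
                }
            )
        if not rows:
            continue
        sub = pd.DataFrame(rows)
        sub["qvalue"] = multipletests(sub["pvalue"], method="fdr_bh")[1]
        records.append(sub.sort_values("qvalue", kind="stable"))
    if not records:
        return pd.DataFrame(
            columns=["set", "term", "overlap", "set_size", "term_size",
                     "universe_size", "pvalue", "overlap_genes", "qvalue"]
        )
    return pd.concat(records, ignore_index=True)


def module_deg_jaccard(modules, degs: dict) -> pd.DataFrame:
    """Jaccard overlap between cluster DEG sets (rows) and modules (columns)."""
    module_sets = _as_sets(modules)
    return jaccard_matrix(degs, module_sets)


def overlap_coefficient(a, b) -> float:
    """Szymkiewicz-Simpson coefficient |A n B| / min(|A|, |B|)."""
    sa, sb = set(a), set(b)
    if not sa or not sb:
        return 0.0
    return len(sa & sb) / min(len(sa), len(sb))


def overlap_coefficient_matrix(modules_by_condition: list) -> pd.DataFrame:
    """Overlap coefficients between all modules of >= 2 conditions.

    Module names are prefixed with their (list-position) condition label, or
    the assignment's own ``condition`` attribute when present.
    """
    if len(modules_by_condition) < 2:
        raise ParameterError("need modules from at least 2 conditions")
    named: dict[str, list[str]] = {}
    for i, assignment in enumerate(modules_by_condition):
        label = getattr(assignment, "condition", None) or f"cond{i}"
        for mod, genes in _as_sets(assignment).items():
            named[f"{label}:{mod}"] = genes
    keys = list(named)
    out = pd.DataFrame(0.0, index=keys, columns=keys)
    for a in keys:
        for b in keys:
            out.loc[a, b] = overlap_coefficient(named[a], named[b])
    return out


@dataclass
class ProgramConsolidation:
    programs: dict[str, dict]  # program -> {"modules": [...], "genes": [...]}
    overlap: pd.DataFrame
    threshold: float

    @property
    def n_programs(self) -> int:
        return len(self.programs)

    def membership(self) -> pd.Series:
        out = {}
        for prog, info in self.programs.items():
            for mod in info["modules"]:
                out[mod] = prog
        return pd.Series(out, name="program")


def consolidate_programs(modules_by_condition: list, threshold: float = 0.5) -> ProgramConsolidation:
    """Merge cross-condition modules into programs by overlap-coefficient graph.

    Edges link module pairs (from different conditions) whose overlap
    coefficient is >= threshold; connected components become programs, each
    with the union gene list of its member modules.  Modules with no
    qualifying edge remain singleton (condition-specific) programs.
    """
    if not (0 < threshold <= 1):
        raise ParameterError("threshold must be in (0, 1]")
    overlap = overlap_coefficient_matrix(modules_by_condition)
    named: dict[str, list[str]] = {}
    cond_of: dict[str, str] = {}
    for i, assignment in enumerate(modules_by_condition):
        label = getattr(assignment, "condition", None) or f"cond{i}"
        for mod, genes in _as_sets(assignment).items():
            named[f"{label}:{mod}"] = genes
            cond_of[f"{label}:{mod}"] = label

    # union-find over qualifying cross-condition edges
    parent = {k: k for k in named}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    keys = list(named)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if cond_of[a] == cond_of[b]:
                continue
            if overlap.loc[a, b] >= threshold:
                parent[find(a)] = find(b)

    components: dict[str, list[str]] = {}
    for k in keys:
        components.setdefault(find(k), []).append(k)
    programs = {}
    ordered = sorted(components.values(), key=lambda mods: (-len(mods), mods[0]))
    for i, mods in enumerate(ordered, start=1):
        genes = sorted(set().union(*[set(named[m]) for m in mods]))
        programs[f"program_{i}"] = {"modules": sorted(mods), "genes": genes}
    return ProgramConsolidation(programs=programs, overlap=overlap, threshold=threshold)
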