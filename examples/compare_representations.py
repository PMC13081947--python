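"""The comparison layer: how cluster markers relate to co-expression modules,
how modules match across conditions, and module-level differential testing.

Run on the full study-shaped fixture, this reproduces the toolkit's central
contrast: broadly active or cluster-graded programs overlap cluster markers,
while the sparse program overlaps none of them -- it is real, but invisible
to the cluster/marker representation.  Takes ~1 minute.
"""

import numpy as np
import pandas as pd

from modulescope import (
    cluster_leiden, consolidate_programs, construct_metacells, cut_modules,
    build_network, default_paper_fixture, differential_module_expression,
    hypergeometric_enrichment, log1p_transform, module_deg_jaccard,
    normalize_total, run_cna, run_dea, run_pca, scale_genes, select_hvgs,
    truncate_pca,
)

seed = 1
X, ann, truth = default_paper_fixture(seed=seed)
X = normalize_total(X)
X = log1p_transform(X)
select_hvgs(X, 2_000)
X = scale_genes(X)
pca = run_pca(X, 30)
clusters = cluster_leiden(truncate_pca(pca, 10), k=15, resolution=1.0, seed=seed)
clusters.index = X.cell_ids
ann.table["cluster"] = clusters.to_numpy()

dea = run_dea(X, clusters, top_n=100)
cna = run_cna(X, pca, ann, clusters, beta=4.0, min_module_size=30, seed=seed)

print("DEG-module Jaccard (rows = clusters, columns = modules):")
jac = module_deg_jaccard(cna.modules, dea.deg_sets)
print(jac.round(2).to_string())
sparse_planted = set(truth.module_genes("sparse"))
best = {c: len(sparse_planted & set(g)) / len(sparse_planted)
        for c, g in cna.modules.module_genes().items()}
sparse_color = max(best, key=best.get)
print(f"\nthe sparse planted program maps to module '{sparse_color}'; its "
      f"Jaccard with every cluster's markers is "
      f"{jac[sparse_color].max():.3f} -- markers never see it.")

print("\ndifferential module expression across conditions (Wilcoxon on MEs):")
dme = differential_module_expression(cna.eigengenes, ann.condition)
sig = dme.query("qvalue < 0.05").sort_values("qvalue")
print(sig[["module", "group_a", "group_b", "mean_difference", "qvalue"]]
      .head(8).round(3).to_string(index=False))

print("\nenrichment of detected modules against the planted gene sets "
      "(hypergeometric, BH-corrected):")
terms = {name: truth.module_genes(name) for name in truth.module_names}
enr = hypergeometric_enrichment(cna.modules, terms, list(X.gene_ids))
top = enr.query("qvalue < 0.05").groupby("set").head(1)
print(top[["set", "term", "overlap", "qvalue"]].to_string(index=False))

print("\nper-condition module consolidation (overlap coefficient >= 0.5):")
assignments = []
for cond in ("control", "saline", "lesion"):
    mask = (ann.condition == cond).to_numpy()
    Xc = X.subset_cells(mask)
    annc = type(ann)(ann.table.loc[mask].copy())
    pcac = truncate_pca(pca, 30)
    pcac.scores = pca.scores[mask]
    mc = construct_metacells(Xc, pcac, annc, k=25, seed=seed)
    net, _ = build_network(mc, beta=4.0)
    modules = cut_modules(
        pd.DataFrame(net.dissimilarity, index=net.genes, columns=net.genes),
        min_module_size=30, expr=mc)
    modules.condition = cond
    assignments.append(modules)
cons = consolidate_programs(assignments, threshold=0.5)
for prog, info in cons.programs.items():
    if len(info["modules"]) > 1:
        print(f"  {prog}: {info['modules']} ({len(info['genes'])} genes) "
              "-- the same program re-detected in each condition")
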