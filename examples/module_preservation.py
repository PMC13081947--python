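"""Module preservation: do modules found in one dataset replicate in an
independent one?

Modules are detected on a reference draw and evaluated on an independent
draw from the same generative model.  Z_density asks whether the module's
genes remain densely inter-connected; Z_connectivity whether the intramodular
hub structure recurs.  Their mean, Z_summary, is read against the
conventional thresholds: >10 strong, 2-10 moderate, <=2 not preserved.
A pseudo-module of random background genes calibrates the null.
"""

import numpy as np
import pandas as pd

from modulescope import (
    ModuleSpec, PreprocessConfig, SyntheticSpec, construct_metacells, generate,
    module_preservation, preservation_verdict, run_cna, run_preprocess,
)


def dataset(seed):
    X, ann, truth = generate(SyntheticSpec(
        n_cells=1_000, n_genes=400, cluster_proportions=[1.0],
        markers_per_cluster=0,
        modules=[ModuleSpec(f"m{i}", s, hub_loading=0.95,
                            peripheral_range=(0.7, 0.95))
                 for i, s in enumerate((50, 40))],
        seed=seed))
    X, pca, clusters = run_preprocess(X, PreprocessConfig(n_pcs=10, seed=seed))
    ann.table["cluster"] = 0
    mc = construct_metacells(X, pca, ann, k=25, seed=seed)
    return X, pca, ann, mc, truth


X, pca, ann, ref_mc, truth = dataset(seed=1)
res = run_cna(X, pca, ann, pd.Series(np.zeros(X.n_cells, dtype=int)),
              beta=4.0, min_module_size=20, seed=1)
detected = res.modules.module_genes()
print("detected modules:", {c: len(g) for c, g in detected.items()})

_, _, _, test_mc, _ = dataset(seed=2)
background = truth.genes[truth.genes["module"] == ""].index
pseudo = list(np.random.default_rng(0).choice(background, 40, replace=False))

report = module_preservation(ref_mc, test_mc, {**detected, "pseudo": pseudo},
                             beta=4.0, n_perm=100, seed=3)
table = report.table[["n_genes", "Z_density", "Z_connectivity", "Z_summary"]].round(1)
table["verdict"] = preservation_verdict(report)
print("\n" + table.to_string())
print("\nplanted modules replicate across independent draws (Z_summary >> 10);"
      "\nthe random pseudo-module sits inside the permutation null (|Z| <= 2).")
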