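# Config-driven pipeline run:  modulescope run examples/pipeline_config.toml --out run_dir
# Omitting "input" makes the simulate stage's output the input of later stages.

seed = 7
stages = ["simulate", "preprocess", "dea", "metacells", "network", "modules", "compare"]

[preprocess]
target_sum = 10000    # per-cell total after library-size normalisation (TP10K)
n_hvgs = 2000         # highly variable genes kept for scaling/PCA
n_pcs = 30            # principal components retained
cluster_pcs = 10      # leading components used for the Leiden KNN graph
knn = 15              # neighbours per cell in the clustering graph
resolution = 1.0      # Leiden resolution (RB modularity)

[dea]
top_n = 100           # marker genes kept per cluster (BH q ascending, positive LFC)
                      # fold changes use pseudocount eps = 1e-6; FDR threshold 0.05

[metacells]
knn = 25              # cells aggregated per metacell
max_shared = 10       # maximum cell overlap between accepted metacells

[network]
method = "pearson"    # gene-gene correlation on metacells
beta = 4.0            # soft power; "auto" scans 1..20 for scale-free fit >= 0.8
                      # (typical usable range 4-12; low values keep weak programs)
min_module_size = 30  # smallest branch accepted as a module
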