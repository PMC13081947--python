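"""Stage orchestration: the DEA track, the CNA track, and the comparison layer.

``run_dea`` and ``run_cna`` are the two in-memory workflows; ``run_pipeline``
is the config-driven front used by the CLI, writing per-stage TSV outputs and
a JSON manifest, skipping stages whose outputs already exist (delete a stage
directory to re-run it).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    CellAnnotation,
    ExpressionMatrix,
    PCAResult,
    read_dense_table,
    read_mtx_triplet,
    write_gmt,
    write_mtx_triplet,
    write_table,
)
from .coexpression import ModuleAssignment, build_network, cut_modules
from .dea import rank_genes_one_vs_rest, tau_scores, top_deg_sets, jaccard_matrix
from .errors import DependencyError, ParameterError
from .metacells import MetacellMatrix, construct_metacells
from .module_stats import (
    compute_eigengenes,
    compute_kme,
    differential_module_expression,
    hub_genes,
    intermodule_correlation,
    module_tau,
)
from .preprocess import (
    PreprocessConfig,
    cluster_leiden,
    log1p_transform,
    normalize_total,
    run_pca,
    scale_genes,
    select_hvgs,
)
from .synthetic import default_paper_fixture

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"

__all__ = ["truncate_pca", "run_dea", "run_cna", "run_pipeline", "CnaResult", "DeaResult"]


def truncate_pca(pca: PCAResult, d: int) -> PCAResult:
    """First-d-components view of a PCA result (for clustering on fewer PCs)."""
    return PCAResult(
        scores=pca.scores[:, :d],
        loadings=pca.loadings[:, :d],
        eigenvalues=pca.eigenvalues[:d],
        variance_explained_fraction=pca.variance_explained_fraction,
        hvg_genes=pca.hvg_genes,
    )


@dataclass
class DeaResult:
    table: pd.DataFrame
    deg_sets: dict
    jaccard: pd.DataFrame
    tau: pd.DataFrame


@dataclass
class CnaResult:
    metacells: MetacellMatrix
    network: object
    scan: object
    modules: ModuleAssignment
    eigengenes: object
    kme: pd.DataFrame
    hubs: dict
    module_tau: pd.DataFrame


def run_dea(X: ExpressionMatrix, clusters, top_n: int = 100) -> DeaResult:
    """One-vs-rest markers, top-N DEG sets, cluster Jaccard and gene Tau."""
    table = rank_genes_one_vs_rest(X, clusters)
    sets = top_deg_sets(table, n=top_n)
    jac = jaccard_matrix(sets, sets)
    tau = tau_scores(
        pd.DataFrame(X.layer_dense("log"), index=X.cell_ids, columns=X.gene_ids),
        clusters,
    )
    return DeaResult(table=table, deg_sets=sets, jaccard=jac, tau=tau)


def run_cna(
    X: ExpressionMatrix,
    pca: PCAResult,
    ann: CellAnnotation,
    clusters,
    *,
    beta: float | None = 4.0,
    metacell_k: int = 25,
    max_shared: int = 10,
    min_module_size: int = 30,
    method: str = "pearson",
    seed: int = 0,
) -> CnaResult:
    """Metacells -> network -> modules -> eigengenes/kME/hubs/module-Tau.

    ``beta=None`` triggers the soft-power scan; the fixed default of 4 (low
    end of the typical 4-12 band) favours sensitivity to weak, sparse
    programs.
    """
    mc = construct_metacells(
        X, pca, ann, k=metacell_k, max_shared=max_shared, seed=seed
    )
    net, scan = build_network(mc, method=method, beta=beta)
    dissim = pd.DataFrame(net.dissimilarity, index=net.genes, columns=net.genes)
    modules = cut_modules(dissim, min_module_size=min_module_size, expr=mc)
    if modules.modules:
        eig = compute_eigengenes(X, modules)
        kme = compute_kme(X, eig)
        hubs = hub_genes(kme, modules, n=10)
        if pd.Series(np.asarray(clusters)).nunique() >= 2:
            mtau = module_tau(eig, clusters)
        else:
            mtau = pd.DataFrame()
    else:  # nothing above the grey pool (e.g. unstructured data)
        eig, kme, hubs, mtau = None, pd.DataFrame(), {}, pd.DataFrame()
    return CnaResult(
        metacells=mc, network=net, scan=scan, modules=modules,
        eigengenes=eig, kme=kme, hubs=hubs, module_tau=mtau,
    )


# ---------------------------------------------------------------------------
# config-driven pipeline
# ---------------------------------------------------------------------------

_STAGE_ORDER = ["simulate", "preprocess", "dea", "metacells", "network", "modules", "compare"]


def _load_config(path: Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".toml", ".tml")):
        import tomllib

        return tomllib.loads(text)
    return json.loads(text)


def _manifest(out_dir: Path, stage: str, params: dict) -> None:
    payload = {
        "toolkit_version": _VERSION,
        "subcommand": stage,
        "parameters": {k: v for k, v in params.items() if not k.startswith("_")},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(payload, indent=2, default=str) + "\n")


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Context:
    """Lazy shared state across stages of one pipeline run."""

    def __init__(self, cfg: dict, out: Path):
        self.cfg = cfg
        self.out = out
        self.seed = int(cfg.get("seed", 0))
        self._cache: dict = {}

    def expression(self) -> tuple[ExpressionMatrix, CellAnnotation]:
        if "expr" in self._cache:
            return self._cache["expr"]
        src = self.cfg.get("input")
        if src is None:
            sim_dir = self.out / "simulate"
            if not sim_dir.exists():
                raise DependencyError(
                    "no input configured and stage 'simulate' has not run"
                )
            X = read_mtx_triplet(sim_dir)
            ann = CellAnnotation(pd.read_csv(sim_dir / "annotation.tsv", sep="\t", index_col=0))
        else:
            src = Path(src)
            X = read_mtx_triplet(src) if src.is_dir() else read_dense_table(src)
            ann_path = self.cfg.get("annotation")
            ann = CellAnnotation(
                pd.read_csv(ann_path, sep="\t", index_col=0)
            ) if ann_path else CellAnnotation(pd.DataFrame(index=X.cell_ids))
        self._cache["expr"] = (X, ann)
        return X, ann

    def preprocessed(self):
        if "pre" in self._cache:
            return self._cache["pre"]
        X, ann = self.expression()
        cfg = self.cfg.get("preprocess", {})
        pcfg = PreprocessConfig(
            target_total=float(cfg.get("target_sum", 10_000)),
            n_hvgs=int(cfg.get("n_hvgs", 2_000)),
            n_pcs=int(cfg.get("n_pcs", 30)),
            knn_k=int(cfg.get("knn", 15)),
            leiden_resolution=float(cfg.get("resolution", 1.0)),
            seed=self.seed,
        )
        X = normalize_total(X, pcfg.target_total)
        X = log1p_transform(X)
        select_hvgs(X, pcfg.n_hvgs)
        X = scale_genes(X)
        pca = run_pca(X, pcfg.n_pcs)
        cluster_pcs = int(cfg.get("cluster_pcs", pcfg.n_pcs))
        clusters = cluster_leiden(
            truncate_pca(pca, cluster_pcs), pcfg.knn_k, pcfg.leiden_resolution, self.seed
        )
        clusters.index = X.cell_ids
        ann.table = ann.table.reindex(X.cell_ids)
        ann.table["cluster"] = clusters.to_numpy()
        self._cache["pre"] = (X, pca, ann, clusters, pcfg)
        return self._cache["pre"]

    def cna(self) -> CnaResult:
        if "cna" not in self._cache:
            X, pca, ann, clusters, _ = self.preprocessed()
            cfg = self.cfg.get("network", {})
            beta = cfg.get("beta", 4.0)
            beta = None if beta in ("auto", None) else float(beta)
            self._cache["cna"] = run_cna(
                X, pca, ann, clusters,
                beta=beta,
                metacell_k=int(self.cfg.get("metacells", {}).get("knn", 25)),
                max_shared=int(self.cfg.get("metacells", {}).get("max_shared", 10)),
                min_module_size=int(cfg.get("min_module_size", 30)),
                method=cfg.get("method", "pearson"),
                seed=self.seed,
            )
        return self._cache["cna"]


def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute the configured stages in dependency order; returns the out dir.

    A stage with an existing output directory is skipped (resume semantics);
    each stage directory receives its outputs as TSV plus a manifest.json.
    """
    cfg = _load_config(Path(config_path))
    out = Path(out_dir or cfg.get("out", "modulescope_run"))
    out.mkdir(parents=True, exist_ok=True)
    stages = cfg.get("stages", _STAGE_ORDER)
    unknown = [s for s in stages if s not in _STAGE_ORDER]
    if unknown:
        raise ParameterError(f"unknown stages: {unknown}")
    ctx = _Context(cfg, out)

    for stage in _STAGE_ORDER:
        if stage not in stages:
            continue
        stage_dir = out / stage
        if stage_dir.exists():
            logger.info("stage %s: outputs exist, skipped", stage)
            continue
        t0 = time.time()
        stage_dir.mkdir(parents=True)
        if stage == "simulate":
            X, ann, truth = default_paper_fixture(seed=ctx.seed)
            write_mtx_triplet(X, stage_dir)
            ann.table.to_csv(stage_dir / "annotation.tsv", sep="\t")
            write_table(truth.cells, stage_dir / "truth_cells.tsv")
            write_table(truth.genes, stage_dir / "truth_genes.tsv")
            _manifest(stage_dir, stage, {"seed": ctx.seed, "preset": "paper"})
        elif stage == "preprocess":
            X, pca, ann, clusters, pcfg = ctx.preprocessed()
            write_table(
                pd.DataFrame(pca.scores, index=X.cell_ids,
                             columns=[f"PC{i+1}" for i in range(pca.scores.shape[1])]),
                stage_dir / "pca_scores.tsv",
            )
            write_table(X.per_gene_stats, stage_dir / "gene_stats.tsv")
            clusters.to_frame().to_csv(stage_dir / "clusters.tsv", sep="\t")
            _manifest(stage_dir, stage, vars(pcfg) | {"seed": ctx.seed})
        elif stage == "dea":
            X, pca, ann, clusters, _ = ctx.preprocessed()
            res = run_dea(X, clusters, top_n=int(cfg.get("dea", {}).get("top_n", 100)))
            write_table(res.table.set_index("gene"), stage_dir / "dea_table.tsv")
            write_gmt(res.deg_sets, stage_dir / "deg_sets.gmt")
            write_table(res.jaccard, stage_dir / "deg_jaccard.tsv")
            write_table(res.tau, stage_dir / "gene_tau.tsv")
            _manifest(stage_dir, stage, {"top_n": cfg.get("dea", {}).get("top_n", 100)})
        elif stage in ("metacells", "network", "modules"):
            res = ctx.cna()
            if stage == "metacells":
                write_table(res.metacells.expr, stage_dir / "metacell_expr.tsv")
                (stage_dir / "membership.json").write_text(
                    json.dumps(res.metacells.membership) + "\n"
                )
            elif stage == "network":
                if res.scan is not None:
                    write_table(res.scan.table, stage_dir / "soft_power_scan.tsv")
                write_table(
                    res.modules.labels.rename("module").to_frame(),
                    stage_dir / "module_assignment.tsv",
                )
            else:
                write_table(res.eigengenes.values, stage_dir / "eigengenes.tsv")
                write_table(res.kme, stage_dir / "kme.tsv")
                write_gmt(res.hubs, stage_dir / "hub_genes.gmt")
                write_table(res.module_tau, stage_dir / "module_tau.tsv")
                write_table(
                    intermodule_correlation(res.eigengenes)
                    if len(res.eigengenes.modules) >= 2
                    else pd.DataFrame(),
                    stage_dir / "intermodule_correlation.tsv",
                )
            _manifest(stage_dir, stage, {"beta": res.network.beta, "seed": ctx.seed})
        elif stage == "compare":
            X, pca, ann, clusters, _ = ctx.preprocessed()
            res = ctx.cna()
            dea_res = run_dea(X, clusters, top_n=int(cfg.get("dea", {}).get("top_n", 100)))
            from .compare_enrich import module_deg_jaccard

            jac = module_deg_jaccard(res.modules, dea_res.deg_sets)
            write_table(jac, stage_dir / "module_deg_jaccard.tsv")
            if len(res.eigengenes.modules) >= 1 and ann.condition is not None:
                dme = differential_module_expression(res.eigengenes, ann.condition)
                write_table(dme.set_index("module"), stage_dir / "differential_me.tsv")
            _manifest(stage_dir, stage, {"seed": ctx.seed})
        logger.info("stage %s finished in %.1fs", stage, time.time() - t0)
    return out
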