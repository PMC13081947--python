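"""Shared fixtures: small hand-built matrices and the study-shaped synthetic
dataset with its canonical analysis (computed once per session)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from modulescope import (
    CellAnnotation,
    ExpressionMatrix,
    cluster_leiden,
    default_paper_fixture,
    log1p_transform,
    normalize_total,
    run_cna,
    run_pca,
    scale_genes,
    select_hvgs,
)
from modulescope.pipeline import truncate_pca

FIXTURE_SEED = 1


def make_expression(counts, cell_ids=None, gene_ids=None) -> ExpressionMatrix:
    counts = np.asarray(counts)
    n, p = counts.shape
    return ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        cell_ids=cell_ids or [f"c{i}" for i in range(n)],
        gene_ids=gene_ids or [f"g{j}" for j in range(p)],
    )


def processed(counts, **kwargs) -> ExpressionMatrix:
    """Counts -> norm/log layers (no HVG/scale)."""
    X = make_expression(counts, **kwargs)
    X = normalize_total(X)
    return log1p_transform(X)


@dataclass
class FixtureAnalysis:
    X: ExpressionMatrix
    ann: CellAnnotation
    truth: object
    pca: object
    clusters: pd.Series
    cna: object


def analyze_fixture(seed: int) -> FixtureAnalysis:
    """The canonical analysis recipe for the study-shaped fixture.

    PCA with 30 components; Leiden on the first 10 (cell identities live in
    the leading components); metacell neighbourhoods in the full 30-PC space;
    network at fixed soft power 4 for sensitivity to weak sparse programs.
    """
    X, ann, truth = default_paper_fixture(seed=seed)
    X = normalize_total(X)
    X = log1p_transform(X)
    select_hvgs(X, 2_000)
    X = scale_genes(X)
    pca = run_pca(X, 30)
    clusters = cluster_leiden(truncate_pca(pca, 10), k=15, resolution=1.0, seed=seed)
    clusters.index = X.cell_ids
    ann.table["cluster"] = clusters.to_numpy()
    cna = run_cna(X, pca, ann, clusters, beta=4.0, min_module_size=30, seed=seed)
    return FixtureAnalysis(X=X, ann=ann, truth=truth, pca=pca, clusters=clusters, cna=cna)


@pytest.fixture(scope="session")
def fixture_analysis() -> FixtureAnalysis:
    return analyze_fixture(FIXTURE_SEED)
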