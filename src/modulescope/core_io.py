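"""Domain containers and readers/writers for the standard formats.

The canonical in-memory orientation is cells x genes everywhere; the on-disk
10x convention (genes as matrix rows) is transposed at read time.  Counts are
held sparse (CSR); derived layers that destroy sparsity ("scaled") are dense.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "CellAnnotation",
    "PCAResult",
    "GeneSetCollection",
    "read_mtx_triplet",
    "write_mtx_triplet",
    "read_dense_table",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
]


def _dedupe(names: list[str]) -> list[str]:
    """Disambiguate duplicate names by appending "-1", "-2", ... in file order."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}-{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


@dataclass
class ExpressionMatrix:
    """A cells x genes UMI count matrix with derived layers.

    Layers:
      "norm"   -- library-size normalised counts (each cell sums to the target)
      "log"    -- natural-log of 1 + normalised counts
      "scaled" -- per-gene z-scores of the log layer (HVG columns only are
                  meaningful; other columns are zero)
    """

    counts: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    layers: dict = field(default_factory=dict)
    per_gene_stats: pd.DataFrame | None = None
    per_cell_stats: pd.DataFrame | None = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)
        n, p = self.counts.shape
        if len(self.cell_ids) != n:
            raise FormatError(
                f"cell_ids length {len(self.cell_ids)} != matrix rows {n}"
            )
        if len(self.gene_ids) != p:
            raise FormatError(
                f"gene_ids length {len(self.gene_ids)} != matrix columns {p}"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("counts must be non-negative")
        if self.per_gene_stats is None:
            self.per_gene_stats = pd.DataFrame(index=self.gene_ids)
        if self.per_cell_stats is None:
            self.per_cell_stats = pd.DataFrame(index=self.cell_ids)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def layer_dense(self, name: str) -> np.ndarray:
        x = self.layers[name]
        return x.toarray() if sp.issparse(x) else np.asarray(x)

    def subset_cells(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        out = ExpressionMatrix(
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            gene_ids=self.gene_ids,
            layers={k: v[idx] for k, v in self.layers.items()},
            per_gene_stats=self.per_gene_stats.copy(),
            per_cell_stats=self.per_cell_stats.iloc[idx].copy(),
        )
        return out


@dataclass
class CellAnnotation:
    """Per-cell categorical metadata: cluster, condition, batch, extras."""

    table: pd.DataFrame

    def __post_init__(self):
        self.table = pd.DataFrame(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def cluster(self) -> pd.Series:
        return self.table["cluster"]

    @property
    def condition(self) -> pd.Series | None:
        return self.table.get("condition")

    @property
    def batch(self) -> pd.Series | None:
        return self.table.get("batch")


@dataclass
class PCAResult:
    """Scores Y (n x d), orthonormal loadings V (p_hvg x d), eigenvalues."""

    scores: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    variance_explained_fraction: float
    hvg_genes: pd.Index | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics) with an optional background universe."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)
    background: list[str] | None = None

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            # preserve order, drop duplicates
            self.sets[name] = list(dict.fromkeys(genes))

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_file(dir_path: Path, stems: list[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = dir_path / (stem + suffix)
            if cand.exists():
                return cand
    raise FormatError(f"none of {stems} found in {dir_path}")


def _read_lines_first_field(path: Path, column: int = 0) -> list[str]:
    out = []
    with _open_maybe_gz(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            out.append(fields[min(column, len(fields) - 1)])
    return out


def read_mtx_triplet(dir_path) -> ExpressionMatrix:
    """Read a 10x-style MatrixMarket triplet directory into cells x genes.

    The feature identity used is the symbol string (second column of the
    features file when present, else the first).  Orientation is resolved by
    matching matrix dimensions against the barcode/feature counts; the 10x
    genes-as-rows layout is transposed.
    """
    dir_path = Path(dir_path)
    mtx_path = _find_file(dir_path, ["matrix.mtx"])
    bc_path = _find_file(dir_path, ["barcodes.tsv", "barcodes.txt"])
    ft_path = _find_file(dir_path, ["features.tsv", "genes.tsv", "features.txt"])

    with _open_maybe_gz(mtx_path) as fh:
        mat = scipy.io.mmread(fh)
    mat = sp.csr_matrix(mat)
    barcodes = _read_lines_first_field(bc_path, column=0)
    # 10x features files carry (id, symbol, type); the symbol is the gene key
    features = _read_lines_first_field(ft_path, column=1)

    r, c = mat.shape
    if r == len(features) and c == len(barcodes):
        mat = sp.csr_matrix(mat.T)  # on-disk genes x cells -> cells x genes
    elif r == len(barcodes) and c == len(features):
        pass
    else:
        bad = bc_path.name if len(barcodes) not in (r, c) else ft_path.name
        raise FormatError(
            f"dimension mismatch: matrix {r}x{c}, {len(barcodes)} barcodes "
            f"({bc_path.name}), {len(features)} features ({ft_path.name}); "
            f"offending file: {bad}"
        )
    return ExpressionMatrix(
        counts=mat,
        cell_ids=pd.Index(_dedupe(barcodes)),
        gene_ids=pd.Index(_dedupe(features)),
    )


def write_mtx_triplet(X: ExpressionMatrix, dir_path) -> None:
    """Write counts in the on-disk 10x convention (genes x cells)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(dir_path / "matrix.mtx"), sp.coo_matrix(X.counts.T))
    (dir_path / "barcodes.tsv").write_text("\n".join(X.cell_ids) + "\n")
    (dir_path / "features.tsv").write_text(
        "".join(f"{g}\t{g}\tGene Expression\n" for g in X.gene_ids)
    )


def read_dense_table(path, orientation: str = "cells_by_genes") -> ExpressionMatrix:
    """Read a delimited text count table with a header row and an id column."""
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise FormatError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path} is empty") from exc
    if df.empty:
        raise FormatError(f"{path} contains no data rows")
    non_numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = non_numeric.isna() & df.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric value at row {df.index[i]!r}, column {df.columns[j]!r} in {path}"
        )
    if orientation == "genes_by_cells":
        df = df.T
    return ExpressionMatrix(
        counts=sp.csr_matrix(df.to_numpy(dtype=float)),
        cell_ids=pd.Index(_dedupe([str(i) for i in df.index])),
        gene_ids=pd.Index(_dedupe([str(c) for c in df.columns])),
    )


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: one tab-separated line per set (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_maybe_gz(Path(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno} has {len(fields)} fields (need >= 3)"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"GMT line {lineno}: set {name!r} has no genes")
            sets[name] = list(dict.fromkeys(genes))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([str(name), description, *map(str, genes)]) + "\n")


def write_table(obj, path) -> None:
    """Write a tabular result as TSV; numeric round-trip is exact to 1e-12."""
    df = obj if isinstance(obj, pd.DataFrame) else pd.DataFrame(obj)
    df.to_csv(path, sep="\t", float_format="%.17g", index=True)


def read_table(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
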