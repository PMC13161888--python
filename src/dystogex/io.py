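"""Readers and writers for every external representation the package
consumes or emits: expression TSV matrices with sample metadata, Matrix
Market UMI count triplets with gene/cell annotations, plain-text gene
lists, and Broad GMT gene-set collections.

Conventions
-----------
* Gene identifiers are HGNC-style symbols; every reader uppercases them
  once at load, and matching elsewhere in the package is case-sensitive
  afterwards.
* All tables are TSV with a header row; decimal point only.
* MTX orientation is cells x genes on disk by default (note the 10x
  convention is the transpose; pass ``orientation="genes-by-cells"`` for
  such files).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import ConsistencyError, FormatError

__all__ = [
    "BulkExpressionDataset",
    "CellDataset",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_mtx_dataset",
    "write_mtx_dataset",
    "read_gmt",
    "write_gmt",
    "read_gene_list",
    "write_gene_list",
]

SAMPLE_COLUMNS = ("donor_id", "age_annotation", "stage", "region", "rin", "sex", "ethnicity")
CELL_COLUMNS = ("cell_id", "sample_id", "cell_type", "region")

MITO_PREFIX = "MT-"
RIBO_PREFIXES = ("RPS", "RPL")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BulkExpressionDataset:
    """Genes x samples expression matrix (RPKM-like, non-negative) plus a
    per-sample covariate table (donor, age, developmental stage, region,
    RIN, sex, ethnicity), aligned on sample identifier."""

    expression: pd.DataFrame  # index = gene symbols, columns = sample ids
    samples: pd.DataFrame     # index = sample ids, columns = SAMPLE_COLUMNS[1:]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.expression.index.duplicated().any():
            dups = self.expression.index[self.expression.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene symbols: {dups}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise FormatError(f"sample metadata missing required column(s): {missing}")
        expr_ids = set(self.expression.columns)
        meta_ids = set(self.samples.index)
        if expr_ids != meta_ids:
            only_expr = sorted(expr_ids - meta_ids)
            only_meta = sorted(meta_ids - expr_ids)
            raise ConsistencyError(
                f"sample mismatch between expression and metadata; "
                f"only in expression: {only_expr}; only in metadata: {only_meta}"
            )
        vals = self.expression.to_numpy()
        if not np.issubdtype(vals.dtype, np.number) or np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise FormatError("expression values must be finite and >= 0")
        rin = pd.to_numeric(self.samples["rin"], errors="coerce")
        if rin.isna().any() or (rin <= 0).any():
            raise FormatError("rin must be numeric and > 0 for every sample")
        # keep metadata in expression column order
        self.samples = self.samples.loc[list(self.expression.columns)]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[0]

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]


@dataclass
class CellDataset:
    """Sparse UMI counts (cells x genes) with cell and gene annotations."""

    counts: sp.csr_matrix     # cells x genes, non-negative integers
    cells: pd.DataFrame       # columns CELL_COLUMNS, one row per matrix row
    genes: pd.DataFrame       # columns gene_symbol, is_mito, is_ribo

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.validate()

    def validate(self) -> None:
        n_cells, n_genes = self.counts.shape
        if len(self.cells) != n_cells:
            raise ConsistencyError(
                f"counts have {n_cells} cells but annotation lists {len(self.cells)}")
        if len(self.genes) != n_genes:
            raise ConsistencyError(
                f"counts have {n_genes} genes but annotation lists {len(self.genes)}")
        for col in CELL_COLUMNS:
            if col not in self.cells.columns:
                raise FormatError(f"cell annotation missing required column: {col}")
        for col in ("gene_symbol", "is_mito", "is_ribo"):
            if col not in self.genes.columns:
                raise FormatError(f"gene annotation missing required column: {col}")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.floor(data))):
            raise FormatError("counts must be non-negative integers")
        if self.genes["gene_symbol"].duplicated().any():
            dups = self.genes["gene_symbol"][self.genes["gene_symbol"].duplicated()].tolist()
            raise FormatError(f"duplicate gene symbols: {dups}")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style): name -> (description, member symbols)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate symbols")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# bulk expression TSV
# ---------------------------------------------------------------------------

def read_expression_matrix(path, metadata_path) -> BulkExpressionDataset:
    """Read a genes x samples TSV plus a sample metadata TSV.

    The expression file has a header row of sample ids and gene symbols in
    the first column.  Metadata must carry a ``sample_id`` column and every
    column in :data:`SAMPLE_COLUMNS`.  Metadata rows are re-indexed to the
    expression column order.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    expr = pd.read_csv(path, sep="\t", index_col=0)
    expr.index = expr.index.astype(str).str.upper()
    expr.index.name = "gene"
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene symbol(s) {dups}")
    meta = pd.read_csv(metadata_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise FormatError(f"{metadata_path}: missing required column 'sample_id'")
    missing = [c for c in SAMPLE_COLUMNS if c not in meta.columns]
    if missing:
        raise FormatError(f"{metadata_path}: missing required column(s) {missing}")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        raise FormatError(f"{metadata_path}: duplicate sample_id rows")
    expr_ids, meta_ids = set(expr.columns), set(meta.index)
    if expr_ids != meta_ids:
        raise ConsistencyError(
            f"samples only in expression: {sorted(expr_ids - meta_ids)}; "
            f"only in metadata: {sorted(meta_ids - expr_ids)}"
        )
    return BulkExpressionDataset(expression=expr, samples=meta.loc[list(expr.columns)])


def write_expression_matrix(dataset: BulkExpressionDataset, path, metadata_path) -> None:
    dataset.expression.to_csv(path, sep="\t")
    dataset.samples.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# sparse UMI counts (Matrix Market)
# ---------------------------------------------------------------------------

def _infer_flags(genes: pd.DataFrame) -> pd.DataFrame:
    genes = genes.copy()
    sym = genes["gene_symbol"].astype(str).str.upper()
    genes["gene_symbol"] = sym
    if "is_mito" not in genes.columns:
        genes["is_mito"] = sym.str.startswith(MITO_PREFIX)
    else:
        genes["is_mito"] = genes["is_mito"].astype(bool)
    if "is_ribo" not in genes.columns:
        genes["is_ribo"] = sym.str.startswith(RIBO_PREFIXES)
    else:
        genes["is_ribo"] = genes["is_ribo"].astype(bool)
    return genes


def read_mtx_dataset(mtx_path, genes_path, cells_path,
                     orientation: str = "cells-by-genes") -> CellDataset:
    """Read a Matrix Market coordinate count file plus gene/cell TSVs.

    ``orientation`` declares the on-disk matrix layout; with
    ``"genes-by-cells"`` (10x convention) the matrix is transposed on load.
    Mitochondrial / ribosomal flags are taken from explicit ``is_mito`` /
    ``is_ribo`` columns when present and otherwise inferred from the
    ``MT-`` / ``RPS`` / ``RPL`` symbol prefixes.
    """
    if orientation not in ("cells-by-genes", "genes-by-cells"):
        raise FormatError(f"unknown MTX orientation: {orientation!r}")
    mat = scipy.io.mmread(str(mtx_path))
    mat = sp.coo_matrix(mat)
    if mat.data.size and (np.any(mat.data != np.floor(mat.data)) or np.any(mat.data < 0)):
        raise FormatError(f"{mtx_path}: counts must be non-negative integers")
    if orientation == "genes-by-cells":
        mat = mat.T
    genes = pd.read_csv(genes_path, sep="\t")
    if "gene_symbol" not in genes.columns:
        raise FormatError(f"{genes_path}: missing required column 'gene_symbol'")
    cells = pd.read_csv(cells_path, sep="\t")
    for col in CELL_COLUMNS:
        if col not in cells.columns:
            raise FormatError(f"{cells_path}: missing required column {col!r}")
    n_cells, n_genes = mat.shape
    if len(genes) != n_genes:
        raise ConsistencyError(
            f"{mtx_path} declares {n_genes} genes but {genes_path} lists {len(genes)}")
    if len(cells) != n_cells:
        raise ConsistencyError(
            f"{mtx_path} declares {n_cells} cells but {cells_path} lists {len(cells)}")
    return CellDataset(counts=mat.astype(np.int64).tocsr(),
                       cells=cells.reset_index(drop=True),
                       genes=_infer_flags(genes).reset_index(drop=True))


def write_mtx_dataset(dataset: CellDataset, mtx_path, genes_path, cells_path) -> None:
    scipy.io.mmwrite(str(mtx_path), dataset.counts.tocoo(), field="integer")
    dataset.genes.to_csv(genes_path, sep="\t", index=False)
    dataset.cells.to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene lists and GMT collections
# ---------------------------------------------------------------------------

def read_gene_list(path) -> list[str]:
    """Plain-text gene list: one symbol per line, '#' starts a comment."""
    symbols: list[str] = []
    seen = set()
    for line in Path(path).read_text().splitlines():
        token = line.split("#", 1)[0].strip()
        if not token:
            continue
        token = token.upper()
        if token not in seen:
            seen.add(token)
            symbols.append(token)
    return symbols


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(genes) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Broad GMT: name TAB description TAB gene TAB gene ...

    Duplicate symbols within one line are collapsed keeping the first
    occurrence; a line with fewer than three fields is rejected with its
    line number.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated "
                              f"fields, got {len(fields)}")
        name, description, raw = fields[0], fields[1], fields[2:]
        genes: list[str] = []
        seen: set[str] = set()
        for g in raw:
            g = g.strip().upper()
            if g and g not in seen:
                seen.add(g)
                genes.append(g)
        if not genes:
            raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no genes")
        if name in sets:
            raise FormatError(f"{path}: line {lineno}: duplicate set name {name!r}")
        sets[name] = (description, genes)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    buf = _io.StringIO()
    for name, (description, genes) in collection:
        buf.write("\t".join([name, description, *genes]) + "\n")
    Path(path).write_text(buf.getvalue())
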