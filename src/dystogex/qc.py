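"""Cell- and gene-level quality control for sparse UMI count data.

Cells are excluded when their log-transformed library size exceeds the
per-sample median by more than ``n_mads`` median absolute deviations
(upper tail only; the MAD is the raw, unscaled median of absolute
deviations unless ``scaled=True`` applies the 1.4826 normal-consistency
constant), or when more than ``max_fraction`` of their UMIs map to
mitochondrial or ribosomal genes (combined by default; a split-threshold
mode tests the two classes separately).  Cell filters run before gene
filters so that gene prevalence is counted on surviving cells only; the
stack is idempotent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyResultError
from .io import CellDataset

__all__ = [
    "QCReport",
    "QCResult",
    "libsize_outlier_mask",
    "mito_ribo_mask",
    "gene_filter",
    "run_qc",
]

logger = logging.getLogger(__name__)

DEFAULT_DROP_NAMED = ("MALAT1",)
MAD_NORMAL_CONSTANT = 1.4826


def _mad_upper_keep(values: np.ndarray, n_mads: float, scaled: bool) -> np.ndarray:
    """Keep flags for a one-sided robust outlier rule: value is an outlier
    iff value > median + n_mads * MAD.  Degenerate MAD (= 0) keeps all."""
    values = np.asarray(values, dtype=float)
    m = np.median(values)
    d = np.median(np.abs(values - m))
    if scaled:
        d *= MAD_NORMAL_CONSTANT
    if d == 0:
        warnings.warn("degenerate MAD (= 0); no cells flagged", stacklevel=2)
        return np.ones(values.size, dtype=bool)
    return ~(values > m + n_mads * d)


def libsize_outlier_mask(dataset: CellDataset, n_mads: float = 3.0,
                         scaled: bool = False) -> np.ndarray:
    """Per-cell keep flag for the library-size rule, computed per sample.

    Library size is the cell's total UMI count; the rule operates on
    natural-log sizes (it is scale-free in the log base).  Samples with
    fewer than 3 cells are warned about and left unfiltered.
    """
    sizes = dataset.library_sizes().astype(float)
    keep = np.ones(dataset.n_cells, dtype=bool)
    log_sizes = np.log(np.maximum(sizes, 1.0))
    for sample, idx in dataset.cells.groupby("sample_id").indices.items():
        if len(idx) < 3:
            warnings.warn(f"sample {sample!r} has < 3 cells; library-size "
                          "filter skipped for it", stacklevel=2)
            continue
        keep[idx] = _mad_upper_keep(log_sizes[idx], n_mads, scaled)
    return keep


def mito_ribo_mask(dataset: CellDataset, max_fraction: float = 0.05,
                   split: bool = False) -> np.ndarray:
    """Per-cell keep flag for the mitochondrial/ribosomal content rule.

    By default the mito and ribo UMI counts are pooled and a cell is
    flagged when their combined fraction of total UMIs strictly exceeds
    ``max_fraction``; with ``split=True`` each class is tested against the
    threshold separately.  Zero-total cells are uninformative and flagged.
    """
    totals = dataset.library_sizes().astype(float)
    mito = np.asarray(dataset.counts[:, dataset.genes["is_mito"].to_numpy()]
                      .sum(axis=1)).ravel().astype(float)
    ribo = np.asarray(dataset.counts[:, dataset.genes["is_ribo"].to_numpy()]
                      .sum(axis=1)).ravel().astype(float)
    zero_total = totals == 0
    if zero_total.any():
        logger.warning("%d cell(s) with zero total UMIs flagged", int(zero_total.sum()))
    safe = np.where(zero_total, 1.0, totals)
    if split:
        flagged = (mito / safe > max_fraction) | (ribo / safe > max_fraction)
    else:
        flagged = (mito + ribo) / safe > max_fraction
    return ~(flagged | zero_total)


def _subset_cells(dataset: CellDataset, keep: np.ndarray) -> CellDataset:
    return CellDataset(counts=dataset.counts[keep],
                       cells=dataset.cells.loc[keep].reset_index(drop=True),
                       genes=dataset.genes.copy())


def gene_filter(dataset: CellDataset, min_cells: int = 3,
                drop_named=DEFAULT_DROP_NAMED
                ) -> tuple[CellDataset, dict[str, int]]:
    """Remove named genes, mitochondrial genes and low-prevalence genes.

    A gene is low-prevalence when it has nonzero counts in fewer than
    ``min_cells`` cells (strict "< min_cells": a gene in exactly
    ``min_cells`` cells is retained).  Apply after the cell filters.
    Returns the filtered dataset and per-category removal counts (each gene
    counted once, in the order named -> mito -> low prevalence).
    """
    named = dataset.genes["gene_symbol"].isin([g.upper() for g in drop_named]).to_numpy()
    mito = dataset.genes["is_mito"].to_numpy() & ~named
    prevalence = np.asarray((dataset.counts > 0).sum(axis=0)).ravel()
    low = (prevalence < min_cells) & ~named & ~mito
    remove = named | mito | low
    report = {
        "n_genes_in": int(dataset.n_genes),
        "n_removed_named": int(named.sum()),
        "n_removed_mito": int(mito.sum()),
        "n_removed_low_prevalence": int(low.sum()),
        "n_genes_out": int((~remove).sum()),
    }
    if report["n_genes_out"] == 0:
        raise EmptyResultError("gene filter removed every gene")
    keep = ~remove
    filtered = CellDataset(counts=dataset.counts[:, keep],
                           cells=dataset.cells.copy(),
                           genes=dataset.genes.loc[keep].reset_index(drop=True))
    return filtered, report


@dataclass
class QCReport:
    """Per-sample cell filtering counts, gene filtering counts, and the
    thresholds that produced them."""

    per_sample: pd.DataFrame   # sample_id, n_cells_in, n_fail_libsize, n_fail_mito_ribo, n_cells_out
    genes: dict[str, int]
    thresholds: dict[str, float] = field(default_factory=dict)

    @property
    def n_cells_in(self) -> int:
        return int(self.per_sample["n_cells_in"].sum())

    @property
    def n_cells_out(self) -> int:
        return int(self.per_sample["n_cells_out"].sum())


@dataclass
class QCResult:
    dataset: CellDataset
    report: QCReport


def run_qc(dataset: CellDataset, n_mads: float = 3.0,
           max_fraction: float = 0.05, min_cells: int = 3,
           drop_named=DEFAULT_DROP_NAMED, scaled_mad: bool = False,
           split_mito_ribo: bool = False) -> QCResult:
    """Full QC stack: library-size rule, mito/ribo rule (cells failing both
    are counted once), then the gene filters on surviving cells."""
    keep_lib = libsize_outlier_mask(dataset, n_mads=n_mads, scaled=scaled_mad)
    keep_mr = mito_ribo_mask(dataset, max_fraction=max_fraction, split=split_mito_ribo)
    keep = keep_lib & keep_mr

    rows = []
    for sample, idx in sorted(dataset.cells.groupby("sample_id").indices.items()):
        rows.append({
            "sample_id": sample,
            "n_cells_in": int(len(idx)),
            "n_fail_libsize": int((~keep_lib[idx]).sum()),
            "n_fail_mito_ribo": int((~keep_mr[idx]).sum()),
            "n_cells_out": int(keep[idx].sum()),
        })
    per_sample = pd.DataFrame(rows)
    if keep.sum() == 0:
        raise EmptyResultError("cell filters removed every cell")

    cells_filtered = _subset_cells(dataset, keep)
    genes_filtered, gene_report = gene_filter(cells_filtered, min_cells=min_cells,
                                              drop_named=drop_named)
    report = QCReport(
        per_sample=per_sample, genes=gene_report,
        thresholds={"n_mads": n_mads, "max_mito_ribo_fraction": max_fraction,
                    "min_cells": float(min_cells)},
    )
    return QCResult(dataset=genes_filtered, report=report)
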