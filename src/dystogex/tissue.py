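"""Tissue-level analysis: one-vs-rest differentially up-regulated gene
sets from a multi-tissue atlas, hypergeometric enrichment of a query gene
list in each tissue's up-set, and hierarchical-clustering leaf orders for
the expression heatmap.

The DEG construction is a documented reconstruction of the convention used
by tissue-enrichment web services: per (gene, tissue), a two-sided Welch
t-test of the tissue's samples against all others on log2(x+1) values; a
gene enters the tissue's up-set when the Bonferroni-adjusted p-value
(family = genes x tissues) is <= alpha AND the mean log2 difference is at
least ``min_abs_log2fc`` (0.58 ~ 1.5-fold).  All thresholds are
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .errors import InputError
from .stats import EnrichmentResult, hypergeom_test

__all__ = [
    "TissueAtlas",
    "DEGSets",
    "one_vs_rest_deg",
    "tissue_enrichment",
    "heatmap_order",
]


@dataclass
class TissueAtlas:
    """Genes x samples expression on linear scale, with per-sample tissue
    labels aligned to the expression columns."""

    expression: pd.DataFrame
    tissue_labels: pd.Series

    def __post_init__(self) -> None:
        if list(self.expression.columns) != list(self.tissue_labels.index):
            self.tissue_labels = self.tissue_labels.reindex(self.expression.columns)
        if self.tissue_labels.isna().any():
            raise InputError("tissue label missing for some samples")
        if self.tissue_labels.nunique() < 2:
            raise InputError("atlas must contain at least 2 tissues")

    @property
    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.tissue_labels))


@dataclass
class DEGSets:
    """Per-tissue up-regulated gene sets and the thresholds that built
    them.  No cross-tissue exclusivity is claimed: a gene may clear the
    one-vs-rest criteria in more than one tissue."""

    sets: dict[str, list[str]]
    params: dict[str, float] = field(default_factory=dict)


def one_vs_rest_deg(atlas: TissueAtlas, alpha: float = 0.05,
                    min_abs_log2fc: float = 0.58) -> DEGSets:
    """Per-tissue up-regulated gene sets by one-vs-rest Welch t-tests on
    log2(x+1) values with Bonferroni control over genes x tissues."""
    labels = atlas.tissue_labels
    counts = labels.value_counts()
    if (counts < 2).any():
        small = sorted(counts.index[counts < 2])
        raise InputError(f"tissue(s) with < 2 samples: {small}")
    tissues = atlas.tissues
    if len(tissues) < 2:
        raise InputError("one-vs-rest needs at least 2 tissues")
    log2 = np.log2(atlas.expression.to_numpy(dtype=float) + 1.0)
    n_genes = log2.shape[0]
    family = n_genes * len(tissues)
    sets: dict[str, list[str]] = {}
    gene_index = atlas.expression.index
    for tissue in tissues:
        in_t = (labels == tissue).to_numpy()
        a, b = log2[:, in_t], log2[:, ~in_t]
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.where(np.isnan(p), 1.0, p)
        diff = a.mean(axis=1) - b.mean(axis=1)
        p_adj = np.minimum(p * family, 1.0)
        up = (p_adj <= alpha) & (diff >= min_abs_log2fc)
        sets[tissue] = list(gene_index[up])
    return DEGSets(sets=sets, params={"alpha": alpha, "correction": "bonferroni",
                                      "family": float(family),
                                      "min_abs_log2fc": min_abs_log2fc})


def tissue_enrichment(query, degs: DEGSets, background) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of the query in each tissue's up-set.

    The background (e.g. a protein-coding gene list) defines the urn; the
    query and every DEG set are intersected with it first.  Bonferroni
    adjustment across the tissues tested.
    """
    bg = list(dict.fromkeys(g.upper() for g in background))
    bg_set = set(bg)
    q = [g.upper() for g in query]
    q_in = [g for g in q if g in bg_set]
    if not q_in:
        raise InputError("query is empty after intersection with the background")
    n, N = len(q_in), len(bg)
    n_tissues = len(degs.sets)
    results = []
    for tissue, genes in degs.sets.items():
        members = [g.upper() for g in genes if g.upper() in bg_set]
        overlap = sorted(set(members) & set(q_in))
        p = hypergeom_test(len(overlap), len(members), n, N)
        results.append(EnrichmentResult(
            unit=tissue, k=len(overlap), K=len(members), n=n, N=N,
            p=p, p_adj=min(1.0, p * n_tissues), overlap_genes=overlap))
    return results


def heatmap_order(atlas: TissueAtlas, genes) -> tuple[list[str], list[str]]:
    """Leaf orders for a genes x tissues heatmap of mean log2(x+1)
    expression, by agglomerative clustering (average linkage, Euclidean).

    Deterministic: scipy's linkage resolves ties by original index, and
    leaves are read off the dendrogram by the standard left-first
    traversal.  With < 2 genes or < 2 tissues the order is the identity.
    """
    genes = [g.upper() for g in genes]
    missing = [g for g in genes if g not in atlas.expression.index]
    if missing:
        raise InputError(f"genes absent from atlas: {missing}")
    log2 = np.log2(atlas.expression.loc[genes].to_numpy(dtype=float) + 1.0)
    labels = atlas.tissue_labels
    tissues = atlas.tissues
    means = np.column_stack([
        log2[:, (labels == t).to_numpy()].mean(axis=1) for t in tissues])

    def _leaf_order(matrix: np.ndarray, names: list[str]) -> list[str]:
        if len(names) < 2:
            warnings.warn("fewer than 2 items; identity order", stacklevel=3)
            return list(names)
        link = sch.linkage(matrix, method="average", metric="euclidean")
        return [names[i] for i in sch.leaves_list(link)]

    gene_order = _leaf_order(means, genes)
    tissue_order = _leaf_order(means.T, tissues)
    return gene_order, tissue_order
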