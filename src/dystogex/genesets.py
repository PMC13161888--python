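"""Hypergeometric over-representation of a query gene list in arbitrary
GMT collections (GO-style biological process / cellular component /
cell-type signatures), with BH-FDR across the sets of one collection, plus
the sensitivity rerun that drops a named exclusion list (e.g. the dopamine
synthesis/transport genes) from the query.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import InputError
from .io import GeneSetCollection
from .stats import EnrichmentResult, bh_fdr, hypergeom_test

__all__ = ["collection_enrichment", "exclusion_rerun"]

logger = logging.getLogger(__name__)


def collection_enrichment(query, collection: GeneSetCollection, background,
                          min_set: int = 3, max_set: int = 2000
                          ) -> list[EnrichmentResult]:
    """One hypergeometric test per gene set, BH-FDR across the collection.

    Sets are intersected with the background first and kept only if their
    size lands in [min_set, max_set]; the FDR family is the surviving sets
    of this one collection.  Results are sorted by raw p.
    """
    bg = list(dict.fromkeys(g.upper() for g in background))
    if not bg:
        raise InputError("background is empty")
    bg_set = set(bg)
    q_in = [g.upper() for g in query if g.upper() in bg_set]
    if not q_in:
        raise InputError("query is empty after intersection with the background")
    n, N = len(q_in), len(bg)
    q_set = set(q_in)

    tested: list[EnrichmentResult] = []
    for name, (_, genes) in collection:
        members = [g for g in genes if g in bg_set]
        if not (min_set <= len(members) <= max_set):
            continue
        overlap = sorted(set(members) & q_set)
        p = hypergeom_test(len(overlap), len(members), n, N)
        tested.append(EnrichmentResult(unit=name, k=len(overlap), K=len(members),
                                       n=n, N=N, p=p, overlap_genes=overlap))
    if not tested:
        raise InputError(f"no gene sets with size in [{min_set}, {max_set}] "
                         "after background intersection")
    adjusted = bh_fdr(np.array([r.p for r in tested]))
    for r, p_adj in zip(tested, adjusted):
        r.p_adj = float(p_adj)
    return sorted(tested, key=lambda r: (r.p, r.unit))


def exclusion_rerun(query, exclude, collection: GeneSetCollection, background,
                    min_set: int = 3, max_set: int = 2000
                    ) -> list[EnrichmentResult]:
    """Re-run the collection enrichment with an exclusion list removed from
    the query (e.g. dopamine pathway members), to test whether enrichment
    survives without them.  Excluded symbols not in the query draw a
    warning; an exclusion that empties the query is an error.
    """
    q = [g.upper() for g in query]
    ex = {g.upper() for g in exclude}
    non_members = sorted(ex - set(q))
    if non_members:
        logger.warning("exclusion list entries not in query: %s", non_members)
    remaining = [g for g in q if g not in ex]
    if not remaining:
        raise InputError("exclusion list removes every query gene")
    return collection_enrichment(remaining, collection, background,
                                 min_set=min_set, max_set=max_set)
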