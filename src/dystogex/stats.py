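"""Shared statistical primitives: exact hypergeometric tail, multiplicity
corrections, and the generic enrichment record used by the tissue and
gene-set analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import InputError

__all__ = [
    "hypergeom_test",
    "bh_fdr",
    "bonferroni",
    "EnrichmentResult",
    "enrichment_frame",
]


def _log_comb(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the background (urn) size, K the size of the annotated set, n the
    query size and k the observed overlap.  Computed exactly in log space by
    summing the point masses from ``k`` to ``min(K, n)`` — stable for any
    input size, no continuity correction, no approximation.
    """
    k, K, n, N = int(k), int(K), int(n), int(N)
    if N < 0 or K < 0 or n < 0 or k < 0:
        raise InputError(f"negative count in (k={k}, K={K}, n={n}, N={N})")
    if K > N or n > N:
        raise InputError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise InputError(f"overlap k={k} exceeds min(K={K}, n={n})")
    if k <= 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    log_pmf = _log_comb(K, i) + _log_comb(N - K, n - i) - _log_comb(N, n)
    p = float(np.exp(logsumexp(log_pmf)))
    return min(p, 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    For sorted p-values p_(1) <= ... <= p_(m) the adjusted value is
    q_(i) = min_{j >= i} (p_(j) * m) / j, capped at 1.  Monotone and always
    >= the raw p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise InputError("bh_fdr expects a 1-d vector of p-values")
    m = p.size
    if m == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = (p[order] * m) / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    np.minimum(adjusted, 1.0, out=adjusted)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def bonferroni(pvalues, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m); family size defaults to len(p)."""
    p = np.asarray(pvalues, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(p * m, 1.0)


@dataclass
class EnrichmentResult:
    """Over-representation of a query gene list in one annotated unit
    (a tissue's up-regulated set, or one curated gene set)."""

    unit: str
    k: int  # overlap size
    K: int  # annotated set size within background
    n: int  # query size within background
    N: int  # background size
    p: float
    p_adj: float = float("nan")
    overlap_genes: list[str] = field(default_factory=list)

    @property
    def proportion_overlap(self) -> float:
        return self.k / self.K if self.K else float("nan")


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Tabular view of a list of enrichment results."""
    return pd.DataFrame(
        {
            "unit": [r.unit for r in results],
            "k": [r.k for r in results],
            "K": [r.K for r in results],
            "n": [r.n for r in results],
            "N": [r.N for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "proportion_overlap": [r.proportion_overlap for r in results],
            "overlap_genes": [",".join(r.overlap_genes) for r in results],
        }
    )
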