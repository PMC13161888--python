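"""Optional matplotlib helpers: the signed -log10(FDR p) stage bar chart
and per-unit enrichment bar charts.  Import cost is deferred so the rest
of the package has no hard matplotlib dependency."""

from __future__ import annotations

import numpy as np
import pandas as pd


def stage_effect_barplot(effects: pd.DataFrame, ax=None, alpha: float = 0.05):
    """Bar chart of signed -log10(FDR-adjusted p) per developmental stage;
    stages significant at ``alpha`` are highlighted."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    sig = effects["p_fdr"] < alpha
    colors = np.where(sig, "tab:green", "tab:gray")
    ax.bar(effects["stage"], effects["signed_neg_log10_fdr"], color=colors)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_ylabel(r"sign(effect) $\times$ $-\log_{10}$(FDR $p$)")
    ax.tick_params(axis="x", rotation=45)
    return ax


def enrichment_barplot(table: pd.DataFrame, unit_col: str = "unit",
                       p_col: str = "p_adj", ax=None, alpha: float = 0.05):
    """Horizontal bars of -log10(adjusted p) per tissue / gene set /
    cell type, sorted by significance."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * len(table) + 1))
    data = table.sort_values(p_col, ascending=False)
    vals = -np.log10(np.maximum(data[p_col].to_numpy(dtype=float), 1e-300))
    sig = data[p_col] < alpha
    ax.barh(data[unit_col], vals, color=np.where(sig, "tab:red", "tab:gray"))
    ax.axvline(-np.log10(alpha), color="black", ls="--", lw=0.8)
    ax.set_xlabel(r"$-\log_{10}$(adjusted $p$)")
    return ax
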