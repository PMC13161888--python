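import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from dystogex.io import BulkExpressionDataset, CellDataset


def make_cell_dataset(counts, cell_types=None, sample_ids=None, gene_symbols=None):
    """Build a CellDataset from a dense array with minimal annotations."""
    counts = np.asarray(counts, dtype=np.int64)
    n_cells, n_genes = counts.shape
    if cell_types is None:
        cell_types = ["T1"] * n_cells
    if sample_ids is None:
        sample_ids = ["S0"] * n_cells
    if gene_symbols is None:
        gene_symbols = [f"G{i:03d}" for i in range(n_genes)]
    cells = pd.DataFrame({
        "cell_id": [f"C{i:03d}" for i in range(n_cells)],
        "sample_id": sample_ids,
        "cell_type": cell_types,
        "region": "striatum",
    })
    genes = pd.DataFrame({
        "gene_symbol": gene_symbols,
        "is_mito": [g.startswith("MT-") for g in gene_symbols],
        "is_ribo": [g.startswith(("RPS", "RPL")) for g in gene_symbols],
    })
    return CellDataset(counts=sp.csr_matrix(counts), cells=cells, genes=genes)


def make_bulk_dataset(expression, stage=None, region=None, rin=None,
                      sex=None, ethnicity=None):
    """Build a BulkExpressionDataset from a genes x samples DataFrame."""
    expression = pd.DataFrame(expression)
    n = expression.shape[1]
    samples = pd.DataFrame({
        "donor_id": [f"D{i}" for i in range(n)],
        "age_annotation": ["x"] * n,
        "stage": stage if stage is not None else ["adulthood"] * n,
        "region": region if region is not None else ["cortex"] * n,
        "rin": rin if rin is not None else [8.0] * n,
        "sex": sex if sex is not None else ["F"] * n,
        "ethnicity": ethnicity if ethnicity is not None else ["E1"] * n,
    }, index=expression.columns)
    return BulkExpressionDataset(expression=expression, samples=samples)


def grid_yeo_johnson_mle(x, step=1e-4, lo=-5.0, hi=5.0):
    """Independent brute-force oracle for the Yeo-Johnson MLE: evaluate
    the Gaussian profile log-likelihood on a dense lambda grid directly
    from the transform's definition and return the argmax."""
    x = np.asarray(x, dtype=float)
    lams = np.arange(lo, hi + step / 2, step)
    pos = x >= 0
    t = np.empty((lams.size, x.size))
    xp1 = x[pos] + 1.0
    with np.errstate(over="ignore"):
        lp = lams[:, None]
        t[:, pos] = np.where(np.abs(lp) < 1e-12, np.log(xp1),
                             (np.power(xp1, lp) - 1.0) / np.where(lp == 0, 1, lp))
        if (~pos).any():
            xm1 = 1.0 - x[~pos]
            lm = 2.0 - lams[:, None]
            t[:, ~pos] = np.where(np.abs(lm) < 1e-12, -np.log(xm1),
                                  -(np.power(xm1, lm) - 1.0) / np.where(lm == 0, 1, lm))
    var = t.var(axis=1)
    llf = -x.size / 2.0 * np.log(var) + (lams - 1.0) * np.sum(
        np.sign(x) * np.log1p(np.abs(x)))
    return float(lams[np.argmax(llf)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
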