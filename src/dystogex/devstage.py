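"""Two-step developmental-stage analysis of a query gene set in bulk brain
expression data.

Step one transforms each query gene's expression (Yeo-Johnson, per-gene
maximum-likelihood lambda) and residualizes it on the technical and
demographic covariates (RIN, ethnicity, sex) by ordinary least squares.
Step two stacks the residuals of all query genes into one long table and,
for each developmental stage independently, regresses the aggregated
residuals on a binary indicator of that stage plus dummy-coded brain
region.  The stage indicator's coefficient and two-sided t-test p-value are
reported; Benjamini-Hochberg adjustment is applied across the stages tested
in one run, and the plotted quantity is sign(effect) * -log10(adjusted p).

The stacked rows are treated as independent observations (plain linear
models, no donor or gene random effects); see the methods note for why this
is a documented statistical limitation rather than an oversight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .errors import (DegenerateInputError, EmptyResultError, InputError,
                     ModelError)
from .io import BulkExpressionDataset
from .stats import bh_fdr

__all__ = [
    "TransformResult",
    "StageAnalysisResult",
    "filter_samples",
    "yeo_johnson",
    "yeo_johnson_transform",
    "residualize_gene",
    "stage_model",
    "run_stage_analysis",
]

logger = logging.getLogger(__name__)

LAMBDA_BOUNDS = (-5.0, 5.0)


# ---------------------------------------------------------------------------
# sample filtering
# ---------------------------------------------------------------------------

def filter_samples(data: BulkExpressionDataset, min_rin: float = 7.0
                   ) -> tuple[BulkExpressionDataset, dict[str, int]]:
    """Drop low-quality and incompletely annotated samples.

    Samples are retained if RIN >= ``min_rin`` (the exclusion rule is the
    strict "RIN < threshold") and stage/region/sex/ethnicity are all
    present.  Returns the filtered dataset and a per-reason removal report.
    """
    meta = data.samples
    rin = pd.to_numeric(meta["rin"], errors="coerce")
    low_rin = rin < min_rin
    annot = meta[["stage", "region", "sex", "ethnicity"]]
    incomplete = annot.isna().any(axis=1) | (annot.astype(str) == "").any(axis=1)
    keep = ~(low_rin | incomplete)
    report = {
        "n_in": int(len(meta)),
        "n_low_rin": int(low_rin.sum()),
        "n_incomplete_metadata": int((incomplete & ~low_rin).sum()),
        "n_out": int(keep.sum()),
    }
    if report["n_out"] == 0:
        raise EmptyResultError(f"no samples survive RIN >= {min_rin} and "
                               "complete-metadata filters")
    kept_ids = meta.index[keep]
    filtered = BulkExpressionDataset(
        expression=data.expression.loc[:, kept_ids].copy(),
        samples=meta.loc[kept_ids].copy(),
    )
    return filtered, report


# ---------------------------------------------------------------------------
# Yeo-Johnson transform
# ---------------------------------------------------------------------------

def yeo_johnson_transform(x, lmbda: float) -> np.ndarray:
    """Yeo-Johnson power transform at a fixed lambda.

    Piecewise in the sign of x, with log branches at lambda = 0 (x >= 0)
    and lambda = 2 (x < 0); strictly increasing in x for any lambda.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    if abs(lmbda) < 1e-12:
        out[pos] = np.log1p(x[pos])
    else:
        out[pos] = (np.power(x[pos] + 1.0, lmbda) - 1.0) / lmbda
    if abs(lmbda - 2.0) < 1e-12:
        out[~pos] = -np.log1p(-x[~pos])
    else:
        out[~pos] = -(np.power(1.0 - x[~pos], 2.0 - lmbda) - 1.0) / (2.0 - lmbda)
    return out


@dataclass
class TransformResult:
    transformed_values: np.ndarray
    lmbda: float


def yeo_johnson(values, lmbda: float | None = None) -> TransformResult:
    """Yeo-Johnson transform with lambda chosen by maximum likelihood.

    The Gaussian profile log-likelihood is maximised over a bounded lambda
    interval [-5, 5] by Brent's method; pass ``lmbda`` to fix the parameter
    instead.  A constant input vector has a flat likelihood and is rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InputError("yeo_johnson requires at least 3 values")
    if not np.all(np.isfinite(x)):
        raise InputError("yeo_johnson requires finite values")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant input: Yeo-Johnson likelihood is flat")
    if lmbda is None:
        res = scipy.optimize.minimize_scalar(
            lambda lm: -scipy.stats.yeojohnson_llf(lm, x),
            bounds=LAMBDA_BOUNDS, method="bounded",
            options={"xatol": 1e-8},
        )
        lmbda = float(res.x)
    return TransformResult(transformed_values=yeo_johnson_transform(x, lmbda),
                           lmbda=float(lmbda))


# ---------------------------------------------------------------------------
# step one: covariate residualization
# ---------------------------------------------------------------------------

def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric rin + dummy-coded sex/ethnicity (first sorted
    level as reference); constant dummy columns are pruned."""
    if covariates[["rin", "sex", "ethnicity"]].isna().any().any():
        raise InputError("missing covariate values")
    cols = {"const": np.ones(len(covariates)),
            "rin": pd.to_numeric(covariates["rin"]).to_numpy(dtype=float)}
    for cat in ("sex", "ethnicity"):
        levels = sorted(covariates[cat].astype(str).unique())
        for level in levels[1:]:  # first sorted level is the reference
            cols[f"{cat}[{level}]"] = (covariates[cat].astype(str) == level
                                       ).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=covariates.index)
    constant = [c for c in X.columns if c != "const" and X[c].nunique() == 1]
    X = X.drop(columns=constant)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ModelError(f"rank-deficient covariate design; columns: {list(X.columns)}")
    return X


def residualize_gene(y, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of one gene's transformed expression on
    RIN + ethnicity + sex (intercept included, so residuals have mean 0)."""
    y = np.asarray(y, dtype=float)
    X = _design_matrix(covariates)
    if len(y) != len(X):
        raise InputError("y and covariates have different lengths")
    fit = sm.OLS(y, X.to_numpy()).fit()
    return np.asarray(fit.resid)


# ---------------------------------------------------------------------------
# step two: per-stage model on aggregated residuals
# ---------------------------------------------------------------------------

def stage_model(residuals: pd.DataFrame, stage: str) -> tuple[float, float]:
    """Regress aggregated residuals on indicator(stage) + region dummies.

    ``residuals`` is the long table with columns gene, sample_id, residual,
    stage, region (one row per gene x sample).  Returns the indicator's OLS
    coefficient and its two-sided t-test p-value.
    """
    for col in ("residual", "stage", "region"):
        if col not in residuals.columns:
            raise InputError(f"residual table missing column {col!r}")
    stages_present = set(residuals["stage"].unique())
    if len(stages_present) < 2:
        raise InputError("residual table must contain at least 2 stages")
    if stage not in stages_present:
        raise InputError(f"target stage {stage!r} absent from residual table")
    indicator = (residuals["stage"] == stage).to_numpy(dtype=float)
    if indicator.min() == indicator.max():
        raise ModelError(f"stage indicator for {stage!r} is constant")
    cols = {"const": np.ones(len(residuals)), "stage": indicator}
    region_levels = sorted(residuals["region"].astype(str).unique())
    for level in region_levels[1:]:
        cols[f"region[{level}]"] = (residuals["region"].astype(str) == level
                                    ).to_numpy(dtype=float)
    X = pd.DataFrame(cols)
    fit = sm.OLS(residuals["residual"].to_numpy(dtype=float), X.to_numpy()).fit()
    j = list(X.columns).index("stage")
    return float(fit.params[j]), float(fit.pvalues[j])


# ---------------------------------------------------------------------------
# end-to-end
# ---------------------------------------------------------------------------

@dataclass
class StageAnalysisResult:
    """Per-stage effect table plus bookkeeping for the run."""

    effects: pd.DataFrame          # stage, effect, p, p_fdr, signed_neg_log10_fdr
    residuals: pd.DataFrame        # long table: gene, sample_id, residual, stage, region
    lambdas: dict[str, float]      # per-gene fitted Yeo-Johnson lambda
    genes_used: list[str]
    genes_missing: list[str]
    genes_dropped_constant: list[str]
    filter_report: dict[str, int]


def run_stage_analysis(data: BulkExpressionDataset, target_genes,
                       stages: list[str] | None = None,
                       min_rin: float = 7.0) -> StageAnalysisResult:
    """Full two-step pipeline: filter -> transform -> residualize ->
    aggregate -> per-stage model -> BH-FDR -> signed -log10(FDR p).

    ``stages`` defaults to every stage present after filtering (sorted by
    first appearance in the metadata); the FDR family is the set of stages
    tested in this run.
    """
    query = [g.upper() for g in target_genes]
    found = [g for g in query if g in data.expression.index]
    missing = [g for g in query if g not in data.expression.index]
    if not found:
        raise InputError(f"no target genes found in dataset; missing: {missing}")
    if missing:
        logger.warning("query genes absent from dataset: %s", missing)

    filtered, filter_report = filter_samples(data, min_rin=min_rin)
    meta = filtered.samples

    frames = []
    lambdas: dict[str, float] = {}
    dropped: list[str] = []
    for gene in found:
        y = filtered.expression.loc[gene].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            dropped.append(gene)
            warnings.warn(f"gene {gene} constant across retained samples; dropped",
                          stacklevel=2)
            continue
        transformed = yeo_johnson(y)
        lambdas[gene] = transformed.lmbda
        resid = residualize_gene(transformed.transformed_values, meta)
        frames.append(pd.DataFrame({
            "gene": gene,
            "sample_id": meta.index,
            "residual": resid,
            "stage": meta["stage"].to_numpy(),
            "region": meta["region"].to_numpy(),
        }))
    if not frames:
        raise EmptyResultError("all target genes constant after filtering")
    residuals = pd.concat(frames, ignore_index=True)

    if stages is None:
        stages = list(dict.fromkeys(meta["stage"]))
    effects, pvals = [], []
    for stage in stages:
        eff, p = stage_model(residuals, stage)
        effects.append(eff)
        pvals.append(p)
    p_fdr = bh_fdr(pvals)
    # adjusted p can underflow to 0 for extreme t statistics; floor it so
    # the plotted statistic stays finite
    neg_log10 = -np.log10(np.maximum(p_fdr, np.finfo(float).tiny))
    table = pd.DataFrame({
        "stage": stages,
        "effect": effects,
        "p": pvals,
        "p_fdr": p_fdr,
        "signed_neg_log10_fdr": np.sign(effects) * neg_log10,
    })
    return StageAnalysisResult(
        effects=table, residuals=residuals, lambdas=lambdas,
        genes_used=[g for g in found if g not in dropped],
        genes_missing=missing, genes_dropped_constant=dropped,
        filter_report=filter_report,
    )
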