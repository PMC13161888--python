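"""Synthetic bulk, single-cell and tissue-atlas generators with planted
ground truth.

Each generator is a pure function of its config (seed included) and returns
the dataset together with a ground-truth table sufficient to score every
downstream analysis (stage-effect recovery, QC flag exactness, cell-type
enrichment recovery, tissue DEG sensitivity/FPR) without re-reading the
config.

Generative models
-----------------
bulk
    log expression = gene baseline + stage effect (target genes only)
    + region offset + beta_rin * (RIN - mean RIN) + sex/ethnicity offsets
    + N(0, noise_sd); the emitted matrix is exp of that, i.e. log-normal
    RPKM-like values, so the downstream power transform has real work to do.
cells
    UMI counts ~ NegativeBinomial(mean = base_mean * fold * size_factor,
    shared dispersion).  Cell size factors are drawn log-uniform on a
    *bounded* interval so that a robust (median + k*MAD) upper outlier rule
    has, by construction, zero false flags on healthy cells; planted
    library-size outliers are scaled far beyond any data-driven threshold,
    and planted high-mito cells are built by binomial thinning of non-mito
    counts into a mitochondrial gene, which preserves the cell's total UMI
    count exactly (the two QC rules stay decoupled).
atlas
    per-sample log2 expression = gene baseline + planted log2 fold change
    for (tissue, gene) pairs + N(0, noise_sd); returned on linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigError
from .io import BulkExpressionDataset, CellDataset
from .tissue import TissueAtlas

__all__ = [
    "DEFAULT_STAGES",
    "BulkSimConfig",
    "CellSimConfig",
    "AtlasSimConfig",
    "SimulatedBulk",
    "SimulatedCells",
    "SimulatedAtlas",
    "generate_bulk",
    "generate_cells",
    "generate_atlas",
    "bulk_gene_universe",
    "cell_gene_universe",
    "atlas_gene_universe",
]

#: The seven developmental stages used throughout: three prenatal, four
#: postnatal, in chronological order.
DEFAULT_STAGES = (
    "early fetal", "mid fetal", "late fetal",
    "infancy", "childhood", "adolescence", "adulthood",
)

DEFAULT_REGIONS = ("frontal cortex", "striatum", "cerebellum", "thalamus")

_MITO_SYMBOLS = ("MT-ND1", "MT-CO1", "MT-ATP6", "MT-CYB", "MT-ND2", "MT-CO2")
_RIBO_SYMBOLS = ("RPS2", "RPL3", "RPS6", "RPL7", "RPS18", "RPL13")


def _filler_genes(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# bulk
# ---------------------------------------------------------------------------

@dataclass
class BulkSimConfig:
    """Configuration for the developmental bulk expression simulator.

    ``stage_effects`` are additive on the (log) transformed scale and apply
    to target genes only; all other knobs are nuisance structure the
    two-step stage model must absorb.
    """

    n_donors_per_stage: int = 6
    stages: tuple[str, ...] = DEFAULT_STAGES
    regions: tuple[str, ...] = DEFAULT_REGIONS
    n_genes: int = 2000
    target_genes: tuple[str, ...] = tuple(f"TG{i:03d}" for i in range(1, 45))
    stage_effects: dict[str, float] = field(default_factory=dict)
    beta_rin: float = 0.1
    beta_sex: float = 0.2
    beta_ethnicity: float = 0.15
    region_sd: float = 0.2
    noise_sd: float = 0.5
    rin_range: tuple[float, float] = (6.0, 10.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_donors_per_stage < 1 or self.n_genes < 1:
            raise ConfigError("n_donors_per_stage and n_genes must be positive")
        if not self.stages:
            raise ConfigError("stages must be non-empty")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if len(self.target_genes) > self.n_genes:
            raise ConfigError("target_genes larger than the gene universe")
        unknown = set(self.stage_effects) - set(self.stages)
        if unknown:
            raise ConfigError(f"stage_effects name unknown stage(s): {sorted(unknown)}")
        if self.rin_range[0] >= self.rin_range[1] or self.rin_range[0] <= 0:
            raise ConfigError("rin_range must be (low, high) with 0 < low < high")


def bulk_gene_universe(config: BulkSimConfig) -> list[str]:
    """Target genes first, then filler symbols up to ``n_genes``."""
    targets = [g.upper() for g in config.target_genes]
    fillers = _filler_genes(config.n_genes - len(targets))
    return targets + fillers


@dataclass
class SimulatedBulk:
    dataset: BulkExpressionDataset
    truth: pd.DataFrame          # columns: stage, effect (planted, transformed scale)
    target_genes: list[str]


def generate_bulk(config: BulkSimConfig) -> SimulatedBulk:
    """Simulate a developmental bulk expression dataset with covariates."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = bulk_gene_universe(config)
    target_set = set(config.target_genes)
    is_target = np.array([g in target_set for g in genes])

    rows = []
    for si, stage in enumerate(config.stages):
        for d in range(config.n_donors_per_stage):
            donor = f"D{si}{d:02d}"
            sex = "M" if rng.random() < 0.5 else "F"
            ethnicity = rng.choice(["E1", "E2", "E3"])
            for region in config.regions:
                rows.append((donor, f"{stage} sample", stage, region, sex, ethnicity))
    samples = pd.DataFrame(
        rows, columns=["donor_id", "age_annotation", "stage", "region", "sex", "ethnicity"])
    samples.index = [f"S{i:04d}" for i in range(len(samples))]
    samples.index.name = "sample_id"
    samples["rin"] = rng.uniform(*config.rin_range, size=len(samples))
    samples = samples[list(("donor_id", "age_annotation", "stage", "region",
                            "rin", "sex", "ethnicity"))]

    baseline = rng.normal(2.0, 1.0, size=config.n_genes)
    # regional differential expression is gene-specific (each gene has its
    # own regional profile), mirroring the structure the tissue analyses
    # are built on
    region_profile = rng.normal(0.0, config.region_sd,
                                size=(config.n_genes, len(config.regions)))
    region_idx = {r: j for j, r in enumerate(config.regions)}
    sample_region = np.array([region_idx[r] for r in samples["region"]])
    eth_levels = ["E1", "E2", "E3"]
    eth_offset = {e: config.beta_ethnicity * i for i, e in enumerate(eth_levels)}

    stage_eff = np.array([config.stage_effects.get(s, 0.0) for s in samples["stage"]])
    rin_centered = samples["rin"].to_numpy() - samples["rin"].mean()
    sample_shift = (
        config.beta_rin * rin_centered
        + np.where(samples["sex"].to_numpy() == "M", config.beta_sex, 0.0)
        + np.array([eth_offset[e] for e in samples["ethnicity"]])
    )

    log_expr = (
        baseline[:, None]
        + np.outer(is_target.astype(float), stage_eff)
        + region_profile[:, sample_region]
        + sample_shift[None, :]
        + rng.normal(0.0, config.noise_sd, size=(config.n_genes, len(samples)))
    )
    expression = pd.DataFrame(np.exp(log_expr), index=pd.Index(genes, name="gene"),
                              columns=samples.index)
    truth = pd.DataFrame({
        "stage": list(config.stages),
        "effect": [config.stage_effects.get(s, 0.0) for s in config.stages],
    })
    dataset = BulkExpressionDataset(expression=expression, samples=samples)
    return SimulatedBulk(dataset=dataset, truth=truth,
                         target_genes=[g.upper() for g in config.target_genes])


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------

@dataclass
class CellSimConfig:
    """Configuration for the sparse UMI count simulator.

    ``specific_sets`` plants cell-type marker genes: within cells of the
    named type, member genes have their NB mean multiplied by
    ``fold_elevation``.  ``libsize_outliers`` / ``mito_fraction_outliers``
    plant cells that violate the QC rules by construction (100x library
    size; ~2x the mito/ribo fraction threshold).  ``n_rare_genes`` plants
    genes expressed in exactly two healthy cells, i.e. below the
    "expressed in < 3 cells" prevalence rule.
    """

    cell_types: dict[str, int] = field(default_factory=lambda: {
        "ExN": 150, "InN": 150, "Ast": 100, "Olig": 100})
    n_genes: int = 2000
    base_mean: float = 0.2
    dispersion: float = 1.0
    specific_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    fold_elevation: float = 5.0
    mito_fraction_outliers: int = 0
    libsize_outliers: int = 0
    libsize_outlier_factor: float = 100.0
    mito_outlier_fraction: float = 0.10
    n_samples: int = 2
    n_mito_genes: int = 2
    n_ribo_genes: int = 2
    include_malat1: bool = True
    malat1_fold: float = 20.0
    n_rare_genes: int = 0
    extra_genes: tuple[str, ...] = ()
    size_factor_log_range: tuple[float, float] = (-0.5, 0.5)
    region: str = "striatum"
    seed: int = 0

    def validate(self) -> None:
        if not self.cell_types or any(c <= 0 for c in self.cell_types.values()):
            raise ConfigError("cell_types must map type -> positive count")
        if self.fold_elevation <= 1:
            raise ConfigError("fold_elevation must be > 1")
        if self.base_mean <= 0 or self.dispersion <= 0:
            raise ConfigError("base_mean and dispersion must be positive")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be positive")
        unknown_types = set(self.specific_sets) - set(self.cell_types)
        if unknown_types:
            raise ConfigError(f"specific_sets name unknown cell type(s): {sorted(unknown_types)}")
        universe = set(cell_gene_universe(self))
        for ctype, gene_list in self.specific_sets.items():
            absent = [g for g in gene_list if g.upper() not in universe]
            if absent:
                raise ConfigError(f"planted genes for {ctype!r} absent from universe: {absent}")
        n_special = (self.n_mito_genes + self.n_ribo_genes
                     + int(self.include_malat1) + self.n_rare_genes)
        if n_special > self.n_genes:
            raise ConfigError("special genes exceed n_genes")


def cell_gene_universe(config: CellSimConfig) -> list[str]:
    """Extra (query) genes, mito genes, ribo genes, MALAT1, then filler
    symbols up to n_genes."""
    if config.n_mito_genes > len(_MITO_SYMBOLS) or config.n_ribo_genes > len(_RIBO_SYMBOLS):
        raise ConfigError("too many mito/ribo genes requested")
    genes = [g.upper() for g in config.extra_genes]
    genes += list(_MITO_SYMBOLS[: config.n_mito_genes])
    genes += list(_RIBO_SYMBOLS[: config.n_ribo_genes])
    if config.include_malat1:
        genes.append("MALAT1")
    if len(genes) > config.n_genes:
        raise ConfigError("extra/special genes exceed n_genes")
    genes += _filler_genes(config.n_genes - len(genes))
    return genes


@dataclass
class SimulatedCells:
    dataset: CellDataset
    cell_truth: pd.DataFrame   # cell_id, planted_libsize_outlier, planted_mito_outlier
    gene_truth: pd.DataFrame   # gene_symbol, is_mito, is_ribo, is_named, is_rare, planted_type


def generate_cells(config: CellSimConfig) -> SimulatedCells:
    """Simulate labelled sparse UMI counts with planted markers and QC
    violations."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = cell_gene_universe(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_genes = config.n_genes

    cell_types = [t for t, c in config.cell_types.items() for _ in range(c)]
    n_cells = len(cell_types)
    cell_ids = [f"C{i:05d}" for i in range(n_cells)]
    sample_ids = [f"SAMP{i % config.n_samples}" for i in range(n_cells)]

    is_mito = np.array([g.startswith("MT-") for g in genes])
    is_ribo = np.array([g.startswith(("RPS", "RPL")) for g in genes])
    is_named = np.array([g == "MALAT1" for g in genes])

    base = np.full(n_genes, config.base_mean)
    base[is_named] *= config.malat1_fold

    fold = np.ones((n_cells, n_genes))
    planted_type = np.array([""] * n_genes, dtype=object)
    for ctype, gene_list in config.specific_sets.items():
        cols = [gene_idx[g.upper()] for g in gene_list]
        rows = [i for i, t in enumerate(cell_types) if t == ctype]
        fold[np.ix_(rows, cols)] = config.fold_elevation
        planted_type[cols] = ctype

    size_factor = np.exp(rng.uniform(*config.size_factor_log_range, size=n_cells))
    mu = base[None, :] * fold * size_factor[:, None]
    theta = config.dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int64)

    n_outliers = config.libsize_outliers + config.mito_fraction_outliers
    if n_outliers > n_cells:
        raise ConfigError("more planted outliers than cells")
    outlier_cells = rng.choice(n_cells, size=n_outliers, replace=False)
    lib_out = outlier_cells[: config.libsize_outliers]
    mito_out = outlier_cells[config.libsize_outliers:]

    # high-mito cells: thin non-mito counts into the first mito gene,
    # preserving the total UMI count of the cell exactly
    if config.mito_fraction_outliers:
        if not config.n_mito_genes:
            raise ConfigError("mito_fraction_outliers requires n_mito_genes >= 1")
        target_gene = int(np.where(is_mito)[0][0])
        keep_p = 1.0 - config.mito_outlier_fraction
        for ci in mito_out:
            row = counts[ci].copy()
            nonmito = np.where(~is_mito)[0]
            kept = rng.binomial(row[nonmito], keep_p)
            moved = int(row[nonmito].sum() - kept.sum())
            row[nonmito] = kept
            row[target_gene] += moved
            counts[ci] = row

    # library-size outliers: scale the whole cell far past any robust cutoff
    if config.libsize_outliers:
        counts[lib_out] = np.round(counts[lib_out] * config.libsize_outlier_factor).astype(np.int64)

    # rare genes: expressed in exactly 2 healthy cells
    rare_flags = np.zeros(n_genes, dtype=bool)
    if config.n_rare_genes:
        planted_cols = set(np.where(planted_type != "")[0])
        n_extra = len(config.extra_genes)
        candidates = [i for i, g in enumerate(genes)
                      if i >= n_extra
                      and not (is_mito[i] or is_ribo[i] or is_named[i] or i in planted_cols)]
        if len(candidates) < config.n_rare_genes:
            raise ConfigError("not enough filler genes for n_rare_genes")
        rare_cols = rng.choice(candidates, size=config.n_rare_genes, replace=False)
        healthy = np.setdiff1d(np.arange(n_cells), outlier_cells)
        for gi in rare_cols:
            counts[:, gi] = 0
            carriers = rng.choice(healthy, size=2, replace=False)
            counts[carriers, gi] = 1
        rare_flags[rare_cols] = True

    cells = pd.DataFrame({
        "cell_id": cell_ids,
        "sample_id": sample_ids,
        "cell_type": cell_types,
        "region": config.region,
    })
    gene_table = pd.DataFrame({
        "gene_symbol": genes,
        "is_mito": is_mito,
        "is_ribo": is_ribo,
    })
    dataset = CellDataset(counts=sp.csr_matrix(counts), cells=cells, genes=gene_table)

    cell_truth = pd.DataFrame({
        "cell_id": cell_ids,
        "planted_libsize_outlier": np.isin(np.arange(n_cells), lib_out),
        "planted_mito_outlier": np.isin(np.arange(n_cells), mito_out),
    })
    gene_truth = pd.DataFrame({
        "gene_symbol": genes,
        "is_mito": is_mito,
        "is_ribo": is_ribo,
        "is_named": is_named,
        "is_rare": rare_flags,
        "planted_type": planted_type,
    })
    return SimulatedCells(dataset=dataset, cell_truth=cell_truth, gene_truth=gene_truth)


# ---------------------------------------------------------------------------
# atlas
# ---------------------------------------------------------------------------

@dataclass
class AtlasSimConfig:
    """Configuration for the multi-tissue expression atlas simulator."""

    tissues: tuple[str, ...] = ("cortex", "striatum", "cerebellum",
                                "liver", "lung", "heart")
    n_samples_per_tissue: int = 20
    n_genes: int = 2000
    elevated: dict[str, tuple[str, ...]] = field(default_factory=dict)
    log2_fc: float = 3.0
    noise_sd: float = 0.3
    extra_genes: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if len(set(self.tissues)) != len(self.tissues):
            raise ConfigError("duplicate tissue labels")
        if self.n_samples_per_tissue < 1 or self.n_genes < 1:
            raise ConfigError("n_samples_per_tissue and n_genes must be positive")
        if self.log2_fc <= 0:
            raise ConfigError("log2_fc must be > 0 for planted up-regulated genes")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        unknown = set(self.elevated) - set(self.tissues)
        if unknown:
            raise ConfigError(f"elevated names unknown tissue(s): {sorted(unknown)}")
        universe = set(atlas_gene_universe(self))
        for tissue, gene_list in self.elevated.items():
            absent = [g for g in gene_list if g.upper() not in universe]
            if absent:
                raise ConfigError(f"planted genes for {tissue!r} absent from universe: {absent}")


def atlas_gene_universe(config: AtlasSimConfig) -> list[str]:
    genes = [g.upper() for g in config.extra_genes]
    if len(genes) > config.n_genes:
        raise ConfigError("extra_genes exceed n_genes")
    return genes + _filler_genes(config.n_genes - len(genes))


@dataclass
class SimulatedAtlas:
    atlas: TissueAtlas
    truth: pd.DataFrame        # gene_symbol, tissue, log2_fc for planted genes


def generate_atlas(config: AtlasSimConfig) -> SimulatedAtlas:
    """Simulate a tissue atlas with planted tissue-elevated genes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = atlas_gene_universe(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    n_per = config.n_samples_per_tissue
    tissue_of_sample = [t for t in config.tissues for _ in range(n_per)]
    sample_ids = [f"A{i:04d}" for i in range(len(tissue_of_sample))]

    baseline = rng.normal(3.0, 1.0, size=config.n_genes)
    log2_expr = baseline[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, len(sample_ids)))
    truth_rows = []
    for tissue, gene_list in config.elevated.items():
        cols = [i for i, t in enumerate(tissue_of_sample) if t == tissue]
        for g in gene_list:
            gi = gene_idx[g.upper()]
            log2_expr[gi, cols] += config.log2_fc
            truth_rows.append((g.upper(), tissue, config.log2_fc))

    expression = pd.DataFrame(np.exp2(log2_expr),
                              index=pd.Index(genes, name="gene"), columns=sample_ids)
    labels = pd.Series(tissue_of_sample, index=sample_ids, name="tissue")
    truth = pd.DataFrame(truth_rows, columns=["gene_symbol", "tissue", "log2_fc"])
    return SimulatedAtlas(atlas=TissueAtlas(expression=expression, tissue_labels=labels),
                          truth=truth)
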