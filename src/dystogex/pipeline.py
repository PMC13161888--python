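"""End-to-end pipeline orchestration.

A run is described by a YAML/dict config: a global seed, an ordered stage
list, and one parameter block per stage.  Stages execute sequentially in
dependency order; each writes its outputs (TSV / MTX / GMT, all plain
text) into the run directory, and a manifest captures the normalized
config, the per-stage seeds and every output path, which suffices to
reproduce the run exactly.  Nothing time-dependent is written, so two runs
from the same config are byte-identical.

The global seed is expanded into independent per-stage substreams through
fixed stage stream ids (a counter scheme), so adding a stage to a config
never perturbs the draws of earlier stages.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import devstage, genesets, qc, specificity, tissue
from .errors import ConfigError, DependencyError
from .io import (GeneSetCollection, read_gene_list, read_gmt, write_gene_list,
                 write_gmt, write_expression_matrix, write_mtx_dataset)
from .simulate import (AtlasSimConfig, BulkSimConfig, CellSimConfig,
                       atlas_gene_universe, cell_gene_universe, generate_atlas,
                       generate_bulk, generate_cells)
from .stats import enrichment_frame

__all__ = ["run_pipeline", "load_config", "demo_config", "KNOWN_STAGES"]

logger = logging.getLogger(__name__)

#: Fixed substream ids per stage; never renumber (the counter scheme is
#: what keeps earlier stages' draws stable when a config adds a stage).
STAGE_STREAMS = {
    "simulate_bulk": 11,
    "simulate_cells": 12,
    "simulate_atlas": 13,
    "ewce": 21,
    "gsea": 22,
}

KNOWN_STAGES = (
    "simulate_bulk", "devstage", "simulate_cells", "qc", "ewce",
    "simulate_atlas", "tissue", "gsea",
)

_STAGE_DEPS = {
    "devstage": ("simulate_bulk",),
    "qc": ("simulate_cells",),
    "ewce": ("qc",),
    "tissue": ("simulate_atlas",),
    "gsea": ("simulate_atlas",),
}


def _stage_seed(global_seed: int, stage: str) -> int:
    stream = STAGE_STREAMS.get(stage, 0)
    ss = np.random.SeedSequence([int(global_seed), stream])
    return int(ss.generate_state(1)[0] % (2**31))


def _check_keys(block: dict, allowed: set[str], path: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"/{path}: unknown key(s) {sorted(unknown)}")


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    return config


def demo_config() -> dict:
    """The bundled demo configuration (synthetic end-to-end run)."""
    from importlib.resources import files
    text = files("dystogex").joinpath("data/demo_config.yaml").read_text()
    return yaml.safe_load(text)


def _query_genes(config: dict) -> list[str]:
    q = config.get("query_genes")
    if q is None:
        q = [f"DG{i:03d}" for i in range(1, 45)]
    return [str(g).upper() for g in q]


class _Run:
    """Mutable state threaded through the stages of one pipeline run."""

    def __init__(self, config: dict, out_dir: Path):
        self.config = config
        self.out_dir = out_dir
        self.seed = int(config.get("seed", 0))
        self.query = _query_genes(config)
        self.outputs: dict[str, list[str]] = {}
        self.state: dict[str, object] = {}

    def params(self, stage: str) -> dict:
        block = self.config.get(stage, {}) or {}
        if not isinstance(block, dict):
            raise ConfigError(f"/{stage}: stage parameters must be a mapping")
        return dict(block)

    def record(self, stage: str, *paths: Path) -> None:
        self.outputs.setdefault(stage, []).extend(p.name for p in paths)

    def path(self, name: str) -> Path:
        return self.out_dir / name

    def require(self, stage: str, key: str):
        if key not in self.state:
            raise DependencyError(
                f"stage {stage!r} requires output {key!r}; run its upstream "
                f"stage(s) {_STAGE_DEPS.get(stage, ())} first")
        return self.state[key]


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def _dataclass_config(cls, params: dict, stage: str, **overrides):
    allowed = set(cls.__dataclass_fields__)
    _check_keys(params, allowed - {"seed"}, stage)
    kwargs = dict(params)
    for key in ("stages", "regions", "target_genes", "tissues", "extra_genes"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    for key in ("specific_sets", "elevated"):
        if key in kwargs and isinstance(kwargs[key], dict):
            kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
    kwargs.update(overrides)
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"/{stage}: {exc}") from exc


def _stage_simulate_bulk(run: _Run) -> None:
    params = run.params("simulate_bulk")
    params.setdefault("target_genes", run.query)
    cfg = _dataclass_config(BulkSimConfig, params, "simulate_bulk",
                            seed=_stage_seed(run.seed, "simulate_bulk"))
    sim = generate_bulk(cfg)
    expr_p, meta_p = run.path("bulk_expression.tsv"), run.path("bulk_samples.tsv")
    write_expression_matrix(sim.dataset, expr_p, meta_p)
    truth_p = run.path("bulk_truth.tsv")
    sim.truth.to_csv(truth_p, sep="\t", index=False)
    genes_p = run.path("query_genes.txt")
    write_gene_list(run.query, genes_p)
    run.record("simulate_bulk", expr_p, meta_p, truth_p, genes_p)
    run.state["bulk"] = sim


def _stage_devstage(run: _Run) -> None:
    params = run.params("devstage")
    _check_keys(params, {"min_rin"}, "devstage")
    sim = run.require("devstage", "bulk")
    result = devstage.run_stage_analysis(sim.dataset, sim.target_genes,
                                         min_rin=float(params.get("min_rin", 7.0)))
    out = run.path("stage_effects.tsv")
    result.effects.to_csv(out, sep="\t", index=False)
    report = run.path("devstage_report.json")
    report.write_text(json.dumps({
        "genes_used": result.genes_used,
        "genes_missing": result.genes_missing,
        "genes_dropped_constant": result.genes_dropped_constant,
        "filter_report": result.filter_report,
    }, indent=2) + "\n")
    run.record("devstage", out, report)
    run.state["stage_effects"] = result


def _stage_simulate_cells(run: _Run) -> None:
    params = run.params("simulate_cells")
    planted_type = params.pop("planted_type", None)
    n_planted = int(params.pop("n_planted", 0))
    params.setdefault("extra_genes", run.query)
    if planted_type is not None and n_planted:
        params.setdefault("specific_sets", {planted_type: run.query[:n_planted]})
    cfg = _dataclass_config(CellSimConfig, params, "simulate_cells",
                            seed=_stage_seed(run.seed, "simulate_cells"))
    sim = generate_cells(cfg)
    mtx, genes_p, cells_p = (run.path("cells_counts.mtx"),
                             run.path("cells_genes.tsv"), run.path("cells_cells.tsv"))
    write_mtx_dataset(sim.dataset, mtx, genes_p, cells_p)
    ct, gt = run.path("cells_cell_truth.tsv"), run.path("cells_gene_truth.tsv")
    sim.cell_truth.to_csv(ct, sep="\t", index=False)
    sim.gene_truth.to_csv(gt, sep="\t", index=False)
    run.record("simulate_cells", mtx, genes_p, cells_p, ct, gt)
    run.state["cells"] = sim


def _stage_qc(run: _Run) -> None:
    params = run.params("qc")
    _check_keys(params, {"n_mads", "max_fraction", "min_cells"}, "qc")
    sim = run.require("qc", "cells")
    result = qc.run_qc(sim.dataset,
                       n_mads=float(params.get("n_mads", 3.0)),
                       max_fraction=float(params.get("max_fraction", 0.05)),
                       min_cells=int(params.get("min_cells", 3)))
    mtx, genes_p, cells_p = (run.path("qc_counts.mtx"),
                             run.path("qc_genes.tsv"), run.path("qc_cells.tsv"))
    write_mtx_dataset(result.dataset, mtx, genes_p, cells_p)
    per_sample = run.path("qc_per_sample.tsv")
    result.report.per_sample.to_csv(per_sample, sep="\t", index=False)
    gene_report = run.path("qc_gene_report.json")
    gene_report.write_text(json.dumps(result.report.genes, indent=2) + "\n")
    run.record("qc", mtx, genes_p, cells_p, per_sample, gene_report)
    run.state["qc"] = result


def _stage_ewce(run: _Run) -> None:
    params = run.params("ewce")
    _check_keys(params, {"n_iter", "scale"}, "ewce")
    result = run.require("ewce", "qc")
    normalized = specificity.normalize_counts(result.dataset,
                                              scale=float(params.get("scale", 1e4)))
    spec = specificity.specificity_scores(
        normalized, result.dataset.cells["cell_type"],
        result.dataset.genes["gene_symbol"])
    enrich = specificity.bootstrap_enrichment(
        spec, run.query, n_iter=int(params.get("n_iter", 10000)),
        seed=_stage_seed(run.seed, "ewce"))
    spec_p = run.path("specificity.tsv")
    spec.scores.to_csv(spec_p, sep="\t")
    out = run.path("ewce_enrichment.tsv")
    enrich.to_csv(out, sep="\t", index=False)
    run.record("ewce", spec_p, out)
    run.state["ewce"] = enrich


def _stage_simulate_atlas(run: _Run) -> None:
    params = run.params("simulate_atlas")
    planted_tissue = params.pop("planted_tissue", None)
    n_planted = int(params.pop("n_planted", 0))
    params.setdefault("extra_genes", run.query)
    if planted_tissue is not None and n_planted:
        params.setdefault("elevated", {planted_tissue: run.query[:n_planted]})
    cfg = _dataclass_config(AtlasSimConfig, params, "simulate_atlas",
                            seed=_stage_seed(run.seed, "simulate_atlas"))
    sim = generate_atlas(cfg)
    expr_p = run.path("atlas_expression.tsv")
    sim.atlas.expression.to_csv(expr_p, sep="\t")
    labels_p = run.path("atlas_labels.tsv")
    sim.atlas.tissue_labels.rename_axis("sample_id").to_csv(labels_p, sep="\t")
    truth_p = run.path("atlas_truth.tsv")
    sim.truth.to_csv(truth_p, sep="\t", index=False)
    run.record("simulate_atlas", expr_p, labels_p, truth_p)
    run.state["atlas"] = sim


def _stage_tissue(run: _Run) -> None:
    params = run.params("tissue")
    _check_keys(params, {"alpha", "min_abs_log2fc"}, "tissue")
    sim = run.require("tissue", "atlas")
    degs = tissue.one_vs_rest_deg(sim.atlas,
                                  alpha=float(params.get("alpha", 0.05)),
                                  min_abs_log2fc=float(params.get("min_abs_log2fc", 0.58)))
    background = list(sim.atlas.expression.index)
    results = tissue.tissue_enrichment(run.query, degs, background)
    gmt_p = run.path("tissue_deg_sets.gmt")
    write_gmt(GeneSetCollection(sets={
        t: (f"one-vs-rest up-regulated in {t}", genes)
        for t, genes in degs.sets.items() if genes}), gmt_p)
    out = run.path("tissue_enrichment.tsv")
    enrichment_frame(results).to_csv(out, sep="\t", index=False)
    gene_order, tissue_order = tissue.heatmap_order(
        sim.atlas, [g for g in run.query if g in sim.atlas.expression.index])
    go_p, to_p = run.path("heatmap_gene_order.txt"), run.path("heatmap_tissue_order.txt")
    write_gene_list(gene_order, go_p)
    Path(to_p).write_text("\n".join(tissue_order) + "\n")
    run.record("tissue", gmt_p, out, go_p, to_p)
    run.state["tissue"] = results
    run.state["degs"] = degs


def _demo_collection(universe: list[str], query: list[str],
                     rng: np.random.Generator) -> GeneSetCollection:
    """A small synthetic GMT: one set genuinely overlapping the query plus
    background-only sets, for exercising the enrichment path end to end."""
    fillers = [g for g in universe if g not in set(query)]
    sets: dict[str, tuple[str, list[str]]] = {
        "PLANTED_QUERY_SET": ("overlaps the query by construction",
                              list(query[:10]) + fillers[:10]),
    }
    for i in range(20):
        members = list(rng.choice(fillers, size=25, replace=False))
        sets[f"RANDOM_SET_{i:02d}"] = ("background draw", members)
    return GeneSetCollection(sets=sets)


def _stage_gsea(run: _Run) -> None:
    params = run.params("gsea")
    _check_keys(params, {"gmt", "exclude", "min_set", "max_set"}, "gsea")
    sim = run.require("gsea", "atlas")
    background = list(sim.atlas.expression.index)
    if "gmt" in params:
        collection = read_gmt(params["gmt"])
    else:
        rng = np.random.default_rng(_stage_seed(run.seed, "gsea"))
        collection = _demo_collection(background, run.query, rng)
        write_gmt(collection, run.path("geneset_collection.gmt"))
        run.record("gsea", run.path("geneset_collection.gmt"))
    results = genesets.collection_enrichment(
        run.query, collection, background,
        min_set=int(params.get("min_set", 3)), max_set=int(params.get("max_set", 2000)))
    out = run.path("geneset_enrichment.tsv")
    enrichment_frame(results).to_csv(out, sep="\t", index=False)
    run.record("gsea", out)
    exclude = params.get("exclude")
    if exclude:
        exclude = ([str(g) for g in exclude] if isinstance(exclude, list)
                   else read_gene_list(exclude))
        rerun = genesets.exclusion_rerun(run.query, exclude, collection, background,
                                         min_set=int(params.get("min_set", 3)),
                                         max_set=int(params.get("max_set", 2000)))
        out2 = run.path("geneset_enrichment_excluded.tsv")
        enrichment_frame(rerun).to_csv(out2, sep="\t", index=False)
        run.record("gsea", out2)
    run.state["gsea"] = results


_STAGE_FUNCS = {
    "simulate_bulk": _stage_simulate_bulk,
    "devstage": _stage_devstage,
    "simulate_cells": _stage_simulate_cells,
    "qc": _stage_qc,
    "ewce": _stage_ewce,
    "simulate_atlas": _stage_simulate_atlas,
    "tissue": _stage_tissue,
    "gsea": _stage_gsea,
}


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config, out_dir=None) -> Path:
    """Execute the configured stages and return the run directory.

    ``config`` is a dict or a path to a YAML file.  Stages run in the
    order given after validation; unknown stage names or parameter keys
    raise :class:`ConfigError` with a path-style pointer.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages = config.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("/stages: a non-empty stage list is required")
    for i, stage in enumerate(stages):
        if stage not in KNOWN_STAGES:
            raise ConfigError(f"/stages[{i}]: unknown stage {stage!r} "
                              f"(known: {list(KNOWN_STAGES)})")
    allowed_top = {"seed", "out_dir", "stages", "query_genes", *KNOWN_STAGES}
    _check_keys(config, allowed_top, "")

    out_dir = Path(out_dir or config.get("out_dir", "dystogex_run"))
    out_dir.mkdir(parents=True, exist_ok=True)
    run = _Run(config, out_dir)

    for stage in stages:
        t0 = time.perf_counter()
        _STAGE_FUNCS[stage](run)
        logger.info("stage %-16s seed=%s outputs=%s (%.2fs)", stage,
                    _stage_seed(run.seed, stage), run.outputs.get(stage, []),
                    time.perf_counter() - t0)

    manifest = {
        "package": "dystogex",
        "config": {k: v for k, v in config.items() if k != "out_dir"},
        "seed": run.seed,
        "stage_seeds": {s: _stage_seed(run.seed, s) for s in stages},
        "outputs": run.outputs,
    }
    (out_dir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return out_dir
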