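# Demo pipeline: synthetic end-to-end run with planted effects.
# The query is a 44-symbol synthetic disease gene set (DG001..DG044); the
# planted structure mirrors the biological expectations the analyses test:
# higher postnatal bulk expression (largest in adulthood, then infancy),
# query genes elevated in the striatum of the tissue atlas, and a query
# subset specific to inhibitory neurons in the single-cell data.
seed: 1
stages:
  - simulate_bulk
  - devstage
  - simulate_cells
  - qc
  - ewce
  - simulate_atlas
  - tissue
  - gsea

simulate_bulk:
  n_donors_per_stage: 6
  n_genes: 500
  noise_sd: 0.5
  # each postnatal effect exceeds the mean of the other six stages, so all
  # four one-vs-rest contrasts are positive, strongest in adulthood then
  # infancy
  stage_effects:
    infancy: 0.9
    childhood: 0.7
    adolescence: 0.8
    adulthood: 1.2

devstage:
  min_rin: 7.0

simulate_cells:
  n_genes: 1500
  planted_type: InN
  n_planted: 20
  libsize_outliers: 5
  mito_fraction_outliers: 3
  n_rare_genes: 4

qc:
  n_mads: 3.0
  max_fraction: 0.05
  min_cells: 3

ewce:
  n_iter: 2000

simulate_atlas:
  n_genes: 1500
  n_samples_per_tissue: 20
  planted_tissue: striatum
  n_planted: 20

tissue:
  alpha: 0.05
  min_abs_log2fc: 0.58

gsea:
  exclude: [DG001, DG002, DG003, DG004, DG005]
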