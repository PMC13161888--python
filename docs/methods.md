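# Methods

`dystogex` asks three questions about a curated query gene set (the
motivating case is the ~44 genes in which variants cause monogenic
dystonia): **when** in brain development the set is preferentially
expressed, **where** (which tissue/region) it is enriched, and **in which
cell populations** its expression is concentrated. Every analysis is
exercised end-to-end on synthetic data with planted ground truth, so the
statistical machinery is testable without any external download.

## Developmental-stage model (`dystogex.devstage`)

Bulk brain expression (RPKM-like values, genes × samples, with donor,
age/stage, region, RIN, sex and ethnicity covariates) is analysed with a
two-step linear modelling procedure:

1. **Filtering.** Samples with RIN < 7 (strict inequality) or incomplete
   stage/region/sex/ethnicity annotation are excluded, with per-reason
   counts reported.
2. **Step one.** Each query gene's expression vector is Yeo-Johnson
   transformed (per-gene λ, maximum Gaussian profile likelihood, Brent
   search bounded to [−5, 5]; the bounded search is reproducible and
   matches a brute-force grid oracle to 1e-3). The transformed values are
   residualized by OLS on `RIN + ethnicity + sex` (dummy coding, first
   sorted level as reference, constant columns pruned; a design still
   rank-deficient after pruning is an error naming the columns).
3. **Step two.** Residuals of all query genes are stacked into one long
   table. For each developmental stage *s* independently, the model
   `residual ~ 1(stage == s) + region` is fitted over all stacked rows;
   the indicator's coefficient is the stage effect and its two-sided
   t-test p-value is reported. Benjamini–Hochberg adjustment is applied
   across the stages tested in one run (default: the seven stages early
   fetal … adulthood — the smallest defensible family), and the plotted
   statistic is sign(effect) × −log10(p_FDR).

λ is estimated **per gene** (configurable in principle; the transform sits
inside the per-gene step, so this is the natural reading). Genes constant
across retained samples are dropped with a warning rather than failing the
run.

**Statistical limitations, quantified.** The stacked step-two regression
treats gene × sample rows as independent; there are no donor or gene
random effects. A sharper consequence, found during calibration work: any
*shared* structure that step one distorts and step two cannot absorb
biases the stacked test, and the bias grows like √(number of genes). If
all query genes carried an identical regional offset, the step-one
projection (RIN/sex/ethnicity) leaves a common region-effect remnant in
every gene's residuals; direct simulation of the procedure on otherwise
iid noise gives null rejection rates at nominal 0.05 of 0.051 (no region
offsets), 0.059 (shared offset, sd 0.2) and 0.099 (sd 0.5). With
gene-specific regional profiles the remnants average out and the test is
approximately calibrated (0.053 at sd 0.2) and turns mildly conservative
for large regional variance (0.030 at sd 0.5), because unabsorbed
per-gene regional deviations inflate the residual variance estimate.
Users applying the model to data with strong covariate–region confounding
should expect the same behaviour.

## Tissue enrichment (`dystogex.tissue`)

Per-tissue up-regulated DEG sets are reconstructed from a linear-scale
atlas by one-vs-rest two-sided Welch t-tests on log2(x+1) values. A gene
enters tissue *t*'s up-set when its Bonferroni-adjusted p-value (family =
genes × tissues) is ≤ α (default 0.05) **and** its mean log2 difference is
≥ 0.58 (≈1.5-fold). These thresholds follow the convention of
tissue-enrichment web services and are parameters, not claims about any
specific precomputed set. Query enrichment per tissue is an exact
hypergeometric upper-tail test against a user-supplied background
(default: all atlas genes; a protein-coding list is the intended input),
Bonferroni-adjusted across tissues. The heatmap companion clusters the
per-tissue mean log2 profiles of the query genes (agglomerative, average
linkage, Euclidean; scipy's deterministic tie-breaking) and returns leaf
orders for genes and tissues.

The hypergeometric tail is computed exactly in log space (gammaln +
logsumexp); BH-FDR is the step-up definition `q_(i) = min_{j≥i}
(p_(j)·m)/j` implemented directly so that it is bit-reproducible against
an independent oracle.

## Single-nucleus QC (`dystogex.qc`)

Cell filters run first, per sample:

* **Library size** — a cell is excluded when its natural-log total UMI
  count exceeds the sample median by more than 3 median absolute
  deviations, upper tail only. The MAD is the *raw* median of absolute
  deviations (the 1.4826 normal-consistency constant is available but off
  by default, taking the rule literally). A zero MAD flags nothing (a
  homogeneous sample should not lose half its cells), and samples with
  fewer than 3 cells are left unfiltered, both with warnings.
* **Mitochondrial/ribosomal content** — a cell is excluded when
  (mito + ribo UMIs) / total UMIs strictly exceeds 5%. The two classes are
  pooled by default ("mitochondrial or ribosomal" read as one rule); a
  split-threshold mode exists. Zero-total cells are uninformative and
  flagged.

Gene filters then operate on surviving cells only: named genes (default
MALAT1), all mitochondrial genes, and genes with nonzero counts in fewer
than 3 cells (strict; a gene in exactly 3 cells stays). The stack is
idempotent, and the QC report counts each cell and gene once.

## Cell-type specificity (`dystogex.specificity`)

Counts are normalized per cell to a fixed total (10⁴) and log1p
transformed. This is a deliberate, documented stand-in for
variance-stabilising count models (regularized NB regression is not
re-implemented here); results are an expression-weighted cell-type
analysis in the EWCE style, not a bit-match of any particular
normalization. The specificity of gene *g* in cell type *c* is

    s(g, c) = mean_c(norm expr of g) / Σ_types mean(norm expr of g)

in [0, 1], rows summing to 1 for every expressed gene (row totals are
summed in canonical sorted order so relabelling cell types permutes
results bit-exactly). Enrichment of a query set in each cell type uses
the **mean** specificity of the query genes found in the expressed-gene
universe (mean and sum are rank-equivalent for equal-size null sets; the
mean is size-interpretable), compared against 10,000 random equal-size
gene sets drawn without replacement from all expressed genes of the
region. The test is one-sided (enrichment), the empirical p-value is
+1-corrected, `p = (1 + #{null ≥ obs}) / (n_iter + 1)`, so it can never
be zero and is floored at 1/(n_iter+1), and BH-FDR runs across the cell
types of one region.

## Gene-set enrichment (`dystogex.genesets`)

Hypergeometric over-representation of the query in each set of a GMT
collection, after background intersection and a [3, 2000] set-size filter
(a common convention; configurable), with BH-FDR across the sets of one
collection (not across collections). `exclusion_rerun` repeats the
analysis with a named gene list (e.g. dopamine synthesis/transport genes)
removed from the query, to ask whether enrichment survives without them.

## Synthetic data (`dystogex.simulate`)

The generators produce the statistical structure the analyses assume —
not the marginal distributions of any real atlas — plus ground-truth
tables sufficient to score every downstream stage.

* **Bulk**: log expression = gene baseline (N(2,1)) + planted stage
  effect (target genes only, additive on the log scale) + gene-specific
  regional profile (N(0, `region_sd`=0.2) per gene × region; regional
  differential expression is gene-specific — the premise of the tissue
  analysis — and a single shared offset would also bias the stacked
  stage test, see above) + RIN/sex/ethnicity effects + N(0,
  `noise_sd`=0.5); the emitted matrix is the exponential, i.e. log-normal,
  so the Yeo-Johnson step has genuine work to do. RIN is uniform on
  (6, 10), so the RIN < 7 filter removes a realistic fraction. Defaults:
  7 stages × 6 donors × 4 regions, 2000 genes, 44 target genes.
* **Cells**: UMI counts are negative binomial with shared dispersion
  (θ = 1) around `base_mean` = 0.2, scaled by a per-cell size factor drawn
  log-uniform on (−0.5, 0.5). The bounded size-factor law is deliberate:
  it gives the robust 3-MAD library-size rule a provable zero false-flag
  margin on healthy cells (max log deviation 0.5 + NB noise ≪ 3 × MAD ≈
  0.75), so planted-violation tests can demand exact recovery. Planted
  library-size outliers are scaled 100-fold; planted high-mito cells are
  built by binomially thinning ~10% of non-mito counts into a
  mitochondrial gene, preserving the cell total exactly so the two cell
  rules stay decoupled. Marker sets multiply the NB mean by
  `fold_elevation` within one cell type; rare genes are planted in
  exactly 2 healthy cells. Defaults: 500 cells in 4 types, 2000 genes,
  2 samples.
* **Atlas**: per-sample log2 expression = gene baseline (N(3,1)) +
  planted log2 fold change for (tissue, gene) pairs + N(0, 0.3), returned
  on linear scale; 6 tissues × 20 samples, 2000 genes.

Every generator is a pure function of its config including the seed.
Because the data are synthetic and clean (no ambient RNA, doublets, batch
effects, donor random effects or heavy-tailed library sizes), passing
tests demonstrate the correctness and calibration of the statistical
machinery — not that real datasets meet these assumptions.

## Pipeline and determinism

The pipeline expands one global seed into fixed per-stage substreams (a
counter scheme over stable stage ids), so adding a stage to a config never
perturbs earlier stages' draws. Outputs are plain text (TSV, Matrix
Market, GMT, JSON manifest) with no timestamps; two runs of the same
config are byte-identical. The bundled demo plants the qualitative
pattern the package is designed to detect: higher postnatal bulk
expression (adulthood strongest, then infancy), query genes elevated in
the striatum of the atlas, and a query subset specific to inhibitory
neurons.

## Problem sizes

Default test and demo sizes (≤ 2000 genes, ≤ 500 cells, ≤ 240 atlas
samples; calibration runs use 200 bulk simulation seeds and 500 bootstrap
replicates at 1000 iterations) were chosen so the whole suite runs in a
few minutes on one CPU while keeping every test's statistical power
adequate for the planted effect sizes.

## Known limitations

* Stacked step-two inference ignores gene–gene and donor-level
  dependence; see the quantified discussion above.
* The library-size normalization stand-in does not model gene-specific
  technical variance.
* No doublet detection, ambient-RNA correction, batch integration,
  clustering or cluster annotation: cells arrive pre-labelled.
* DEG-set construction is a parameterized reconstruction of a common
  convention, not a reproduction of any service's precomputed sets.
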