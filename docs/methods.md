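# Methods

`striaseq` re-implements, as a reusable and fully tested pipeline, the
cell-type-resolved analysis stack used in case–control snRNA-seq studies of
postmortem brain: droplet quality control, reference-based cell annotation,
pseudobulk differential expression with nested contrasts, gene-set
enrichment with pathway networks and a sex-interaction score, consensus
transcription-factor→gene network inference, and AUCell-style gene-set
activity scoring. Everything runs end to end on a seeded synthetic cohort
generator with known ground truth, so each stage's recovery and calibration
properties are testable without access to restricted human data.

## Synthetic cohort generator (`synthio`)

The generator emulates a balanced postmortem design: `n_individuals = 12`
(six case–control pairs matched on sex, with age, postmortem interval and
RNA integrity drawn per pair), two striatal regions sampled per individual,
and ten cell types with exclusive marker genes. Counts are negative binomial
via a gamma–Poisson draw: the mean of gene *g* in cell *c* is
`libsize_c × p_t(g) × (planted multipliers)` with `libsize ~ LogNormal(log 2500, 0.35)`
and gene-wise dispersions log-normally spread around `nb_dispersion = 0.3`
(field-typical overdispersion for UMI counts). A per-individual × gene
multiplicative effect (`indiv_effect_sd = 0.1` on the log2 scale) supplies
biological replicate variation so that pseudobulk inference faces realistic
between-individual noise.

Per-type profiles share a log-normal gene-abundance backbone; each type gets
40 exclusive markers boosted 8× (and suppressed 20× elsewhere), which drives
both label transfer and marker detection. Mitochondrial genes carry ~2% of
the intact-cell profile mass and ribosomal genes ~5%.

Ground-truth effects multiply NB means:

* **Differential expression** — `2^log2FC` on one gene in case cells of one
  type, optionally restricted to one sex (`F_only`/`M_only`), matching how
  sex-specific disease effects would manifest.
* **Regulons** — a standard-normal latent factor per cell scales the TF and
  its targets by `exp(c·z − c²/2)` (mean-preserving), inducing TF–target
  co-expression at coupling `c`.
* **Gene-set activity** — a fold-change multiplier on every member of a gene
  set in case cells of one type.

Artifacts are planted after the clean draw: doublets add the counts of a
random different-type cell from the same sample; damaged nuclei have their
transcriptome binomially thinned to 60% and mitochondrial UMIs injected to a
25–55% mitochondrial fraction; empty droplets are shallow Poisson draws from
the cohort-average (ambient) profile; ambient contamination rebuilds a fixed
fraction of every cell's UMIs from that profile. Nuclear (intronic) fraction
is Beta(20, 2) for true nuclei and Beta(2, 20) for empty droplets. Cluster
labels mimic what over-clustering does on real data: damaged and empty
droplets separate into their own clusters (their profiles are genuinely
distinct), while doublets co-cluster with their first constituent type.

All randomness flows from one master seed through named substreams
(`profiles`, `individuals`, `cells`, `counts`, `artifacts`, `noise`), so a
config is bit-reproducible and stages can be regenerated independently.

**Deliberate departures from real tissue.** Cell-type proportions are
compressed (most prevalent type 23% rather than the ~60% oligodendrocyte
share of real striatum) so that at desk scale (400 cells per sample) every
type clears the 20-cell pseudobulk floor after QC losses; with realistic
proportions the rare interneuron types could never be tested downstream.
The generator also does not model sequencing-read noise, UMI collisions,
batch chemistry effects, spatial anatomy, or cell-type-specific dispersion
differences — so passing tests demonstrate the correctness and calibration
of the statistical machinery under the stated model, not robustness to
every artifact of real data.

## Droplet QC (`qc`)

Three flaggers reproduce the standard triage semantics:

* **Empty droplets** — a two-component 1-D Gaussian mixture on the nuclear
  fraction finds the ambient/nuclear boundary; cells in the low component
  are flagged unless `nuclear_fraction > 0.50` (`nf_rescue`) or
  `umi_total ≥ 1000` (`umi_rescue`). Unimodal inputs yield no flags, with a
  warning.
* **Doublets** — a hybrid score in [0, 2], the sum of two components each
  min-max normalized to [0, 1]: (a) detection of the marker panel of the
  cell's *second-best* cluster (high only when markers of two mutually
  exclusive clusters are co-detected), and (b) the fraction of simulated
  doublets among the cell's 20 nearest neighbors in 30-component PCA space.
  Simulated doublets are heterotypic pair sums — homotypic pairs are
  excluded because depth-doubled majority-type cells otherwise pollute the
  simulation and inflate false positives in the largest cluster. The call
  threshold is fixed at 1.0, so a call needs support from both components.
  With a single cluster, component (b) alone is scaled to [0, 2].
* **Damaged nuclei** — a two-component EM mixture of linear regressions of
  mitochondrial fraction on detected genes (intact: flat and low; damaged:
  elevated), initialized from the 10th/90th mitochondrial-fraction
  quantiles, at most 200 iterations, log-likelihood tolerance 1e-6. Cells
  with damaged-component posterior strictly above 0.75 are flagged;
  components whose fitted levels coincide (within 3e-3) are treated as one
  population and nothing is flagged.

The cluster rule removes any cluster in which strictly more than 10% of
cells carry a flag; flagged cells inside retained clusters are also removed
individually (the conservative reading). `run_qc` groups cells per
individual before flagging; at desk scale this gives each mixture fit
~800 cells, enough for stable boundaries, while preserving the
per-sample-batch spirit of the per-well analysis.

## Annotation (`annotate`)

Label transfer is centroid-based: Spearman correlation of each cell's
log-normalized profile with every reference type centroid over the top
1000 shared highly variable genes, converted to prediction scores by
`softmax(30 × corr)`; the softmax scale of 30 turns the typical
own-vs-other correlation gap (~0.1–0.4 on synthetic data) into confident
scores while leaving genuinely ambiguous cells below the 0.5 cutoff, at
which they are labeled `unassigned`. A second pass re-scores cells of a
designated parent class (medium spiny neurons in the striatal setting)
against a subtype reference with the same cutoff.

Markers are one-vs-rest calls per biological replicate (log2 fold-change ≥ 1
on log1p-CPM means, detection-rate difference ≥ 0.2, one-sided rank-sum
p < 0.05) kept only when reproducible in ≥ 80% of replicates containing the
type. Abundance differences are tested on logit proportions (Haldane 0.5
offset) with a mixed model (random intercept per individual; OLS with
individual-clustered errors as the singular-fit fallback); p-values use
between-within t degrees of freedom (individuals − model terms) because the
group factor varies at the individual level and normal-based Wald p-values
are anticonservative with 12 individuals. BH correction across types.

## Pseudobulk DE (`pseudobulk`, `demodel`)

UMI counts are summed per (individual, region, cell type); profiles from
fewer than 20 cells are dropped; mitochondrial/ribosomal genes and genes
with mean count < 5 are removed; responses are
`log2((count + 0.5) / (libsize + 1) × 1e6)`. The gene detection rate (GDR,
fraction of genes detected per profile) is computed before gene filtering
and enters the model as a covariate.

One intercept-free nested factor encodes cell type × diagnosis × sex ×
region (or cell type × treatment with matched-pair dummies in the paired
design), plus Age, PMI, RIN and GDR (z-scored) and any surrogate variables.
Per-gene inference is weighted generalized least squares:

* **Precision weights** — a lowess trend (span 0.5) of √(residual SD) on
  mean log2 count, inverted to fourth-power weights at each observation's
  fitted log-count; multiplied by per-sample quality weights estimated from
  trend-standardized residuals (leverage-corrected mean squared residual
  per sample, normalized to geometric mean 1).
* **Duplicate correlation** — per-gene intraclass correlation of model
  residuals over individuals (one-way ANOVA with unbalanced-size
  correction), consensus `tanh(mean(atanh ρ_g))`; used as a known
  compound-symmetric correlation in the GLS covariance. The consensus is
  computed on unweighted residuals — it is a single robust summary and
  insensitive to the precision weighting.
* **Surrogate variables** — SVD of the design residual matrix; in `auto`
  mode a permutation parallel analysis (20 within-gene permutations of the
  data, re-residualized against the design) keeps leading components whose
  singular value exceeds the permutation maximum. Comparing against the
  permutation maximum rather than an interpolated 95th percentile keeps the
  false-component rate at 1/(B+1) ≈ 5% exactly; with 20 permutations the
  interpolated quantile is noisy and measurably anticonservative. SVs are
  re-orthogonalized against the design.
* **Moderation** — residual variances are shrunk by moment matching on
  log s² (scaled inverse-chi-square prior; trigamma inversion by Newton's
  method); moderated t uses residual + prior degrees of freedom. Prior df 0
  reproduces ordinary t exactly; identical variances drive the prior df to
  infinity and shrink completely.

Contrast families are linear combinations of nested levels: `overall`
averages (case − control) over sex × region within the scope; `within_F` /
`within_M` restrict to one sex; `sex_interaction` is the female difference
minus the male difference; `treatment` is the per-type paired contrast.
Scopes are single types or pooled Neuron/Glia/All averages. When a level is
unobserved (a profile dropped by the 20-cell rule) the contrast averages the
observed levels.

FDR uses Storey-type q-values with a covariate-dependent null proportion:
for each λ in 0.05…0.95, `1{p > λ}` is regressed on a spline basis of the
covariate (mean log-CPM for genes, set size for pathways) by lightly
ridge-penalized logistic regression; the λ-profile is smoothed by a
precision-weighted linear trend and read off at λ = 0.95. The covariate is
winsorized at its 5th/95th percentiles and the ridge penalty keeps π₀(x)
near-constant unless the data demand otherwise — both guards against the
tail excursions that unpenalized spline fits show at 10⁴ tests. q-values
are π₀(x)·BH step-up values: with π₀ ≡ 1 the procedure *is*
Benjamini–Hochberg, which is also the fallback below 50 tests. As with any
Storey-type estimator, a q-value can fall below its p-value when π₀ < 1.
`adj.P.Val.Within` adjusts within one cell-type scope; `adj.P.Val.Between`
pools all scopes of a contrast family.

## Enrichment (`enrich`)

Preranked GSEA uses the weighted Kolmogorov–Smirnov running sum (hit steps
∝ |statistic| with weight exponent 1, miss steps 1/(N−n)); ES is the
extremum of the walk. Significance comes from gene-label permutations
(default 10,000; permuted sets of the same size are cached and shared), the
NES divides by the mean |permuted ES| of the same sign, and the p-value uses
the add-one permutation estimator within the same-sign permutations.
Leading-edge genes are the members at or before (after, for negative ES)
the extremum. Significant pathways (q < 0.05) are linked when the overlap
coefficient `|A∩B| / min(|A|,|B|)` of their leading edges is ≥ 0.5 and
clustered by greedy modularity; singletons are reported alongside.

The sex-interaction score per gene is
`sign(log2FC_F)·(−log10 p_F) − sign(log2FC_M)·(−log10 p_M)`, with
`sign(0) = 0` and p floored at 1e-300. Ortholog mapping expands one-to-many
relations, drops unmapped members with a count, and deduplicates.

## Consensus GRN (`grn`)

Before inference the most prevalent cell type is subsampled to the count of
the second most prevalent (generalizing the practice of down-sampling
oligodendrocytes). Per individual and per stochastic run, every non-TF gene
is regressed on all TF expressions (log-CPM, so library size cannot
masquerade as co-regulation) by a randomized stump forest: each of 50 trees
draws a 50% row subsample and a √q-sized TF subset, proposes two random
split thresholds per candidate, and credits the variance-reduction gain of
the best split to its TF — evaluated for all targets simultaneously, which
makes the scorer fast enough for thousands of target regressions per run.
Importances are normalized to sum to 1 per target and edges are kept in
decreasing order until 95% cumulative importance mass.

Reproducibility filtering is two-tier: an edge must appear in ≥ ⌈0.8·R⌉ of
R runs within an individual (unanimity for R = 3 or 4; a `strict` flag
switches to the literal >80% reading), and then in ≥ ⌈0.8·N⌉ of N
individuals (10 of 12). Importances are averaged at each tier and both
support fractions are reported. Optional pruning against a TF→target
allowlist (standing in for motif-based promoter filtering) groups surviving
edges into regulons.

The regulon-recovery study (5 regulons × 15 targets among 200 genes,
12 individuals × 4 runs, coupling 0.6) uses homogeneous baseline profiles
(no marker structure): with marker-structured types, cell-type composition
itself induces strong, individually-reproducible TF–gene co-expression, and
the consensus network correctly reports those compositional edges — which
is precisely why the original workflow downsamples the majority type and
prunes by promoter motifs. The homogeneous cohort isolates the
planted-regulon contract that the aggregation tiers are meant to guarantee.

## Activity (`activity`)

Within each cell, genes are ranked by decreasing count with ties broken by
a seeded random jitter (< 1, so only integer ties reorder). For a set with
m ranked members and threshold k = ⌊0.05·n_genes⌋, the score is
Σ_{j≤k} R(j) normalized by its maximum m·k − m(m−1)/2, i.e. the area under
the recovery curve, 1 iff the set occupies the top ranks. The score depends
only on ranks and is invariant to monotone count transforms. Scores are
averaged into pseudobulk by (individual, region, cell type) with the same
20-cell floor as DE.

Activity regressions are OLS with the design-appropriate formula — sample
level `score ~ Dx + Age + PMI + RIN + Sex`, cell-type level
`score ~ Dx:Celltype + Celltype + Age + PMI + RIN + log(n_cells)`, and the
paired forms `score ~ Tx + Pair` / `score ~ Celltype:Tx + Celltype + Pair`.
Estimates are oriented as case − control regardless of dummy coding.
FDR is joint across gene sets × cell types (covariate-aware when ≥ 50
tests, BH otherwise).

## Problem sizes used in the test suite

The calibration studies run at deliberately scaled-down sizes chosen so the
Monte Carlo error of each check is small relative to its acceptance margin:
null-FDR calibration uses 200 replicate cohorts of 12 individuals ×
2 regions × 6 cell types × 2000 genes (150 cells per sample, no surrogate
variables — the null cohort has no batch structure for them to find);
activity-regression calibration uses 500 null simulations at the pseudobulk
level; GSEA permutation calibration uses 200 random sets on a 1000-gene
ranking; confidence-interval coverage uses 500 simulations.

## Known limitations

* The q-value machinery assumes p-values that are uniform under the null;
  the pseudobulk moderated-t p-values are mildly anticonservative at the
  raw level under strong NB overdispersion (the FDR-level calibration is
  what the suite verifies).
* The doublet score's component normalization is per-sample min-max; in a
  sample with no doublets at all the top clean cell defines the scale and
  can exceed the threshold.
* The EM mixture for damaged cells assumes Gaussian residuals on the
  mitochondrial fraction; heavily zero-inflated mito fractions would call
  for a beta-regression variant.
* Label transfer is centroid-based and does not model within-type continua;
  a query population absent from the reference is absorbed into its nearest
  centroid or `unassigned` rather than being discovered.
* The stump forest scores marginal TF–target dependence; purely
  interaction-driven regulation (a target responding only to TF pairs)
  would be invisible to it.
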