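# Methods

## The generative model

### Single-cell counts

Each virtual cohort has `n_tumors` (default 8) tumors and a fixed cell-type
roster (default 10: epithelial, endothelial, fibroblast, macrophage, T, B,
NK, plasma, erythrocyte, adipocyte; the last two flagged fragile). Counts
follow a gamma–Poisson (negative binomial) model:

- **Archetypes.** Per-type mean expression over `n_genes` (default 1200)
  genes is a shared log-normal baseline (σ = 1.2) times per-type log-normal
  deviations (σ = 0.8). Named marker blocks (hemoglobin, adipocyte,
  endothelial, stress-response, canonical-histone, mitochondrial — 77 genes
  with HGNC-style names, mutually disjoint) are then rescaled so each block
  holds a fixed read share within each type's profile: hemoglobin 60% of an
  erythrocyte's reads and ~0.01% elsewhere, adipocyte markers 30% of an
  adipocyte, endothelial markers 25% of an endothelial cell, mitochondrial
  transcripts 8% everywhere (the poly-A-visible level), histones 3% in
  epithelial / 1% elsewhere, stress genes 0.4% at baseline. Anchoring block
  shares rather than leaving them to chance keeps the bulk-level protocol
  effects well defined.
- **Patient effects.** Each tumor multiplies every archetype by per-gene
  log-normal factors (σ = `patient_effect_sd`, default 0.30), giving
  inter-patient heterogeneity shared across that tumor's cell types.
- **Cells.** Per-tumor compositions are Dirichlet draws (concentration 60)
  around a realistic HGSOC mean (epithelial 0.40 … adipocyte 0.01); cell
  tallies use largest-remainder apportionment with every positive-prior type
  kept at ≥ 1 cell. Library sizes are log-normal (mean 1500, σ = 0.35)
  scaled by a per-type mRNA-content factor (epithelial 1.9, lymphocytes 0.6,
  erythrocyte 0.25, …). Gene counts are Poisson with gamma-multiplied means
  (dispersion 0.15); dispersion → 0 degenerates cleanly to Poisson.

Structural randomness (archetypes, patient effects, compositions) is driven
by the config's `rng_seed`; cell- and read-level sampling by the operation
seed. All streams are named, so identical (config, seed) reruns are
bit-identical.

### Bulk libraries and protocol effects

A bulk sample for tumor *t* under protocol *P* mixes the tumor's observed
per-type mean profiles with weights equal to the tumor's RNA shares times
*P*'s retention factors, renormalized; the recorded ground truth is exactly
these post-retention RNA fractions. Effects:

- **Dissociation** removes fragile types (erythrocyte and adipocyte
  retention default 0 when dissociated — red-cell lysis and adipocyte
  destruction) and multiplies the stress block by `stress_induction`
  (default 3). Dissociation is modeled as composition change plus stress
  induction, not per-gene noise: the relative increase of surviving types'
  markers is an arithmetic consequence of removing the fragile types.
- **Enrichment chemistry** multiplies one block before the multinomial draw:
  under poly-A capture the histone block is shrunk by a retention factor,
  under rRNA depletion the mitochondrial block by a depletion factor. When
  these factors are left at their defaults they are resolved per tumor: a
  target fold ratio is drawn uniformly inside the calibration window
  (histone rRNA/polyA in [1.7, 10], mito polyA/rRNA in [10, 30]) and the
  factor is solved by a small fixed point so the *depth-normalized* expected
  ratio equals the target exactly — the two blocks couple through the
  renormalization and an uncorrected factor would bias the realized ratio by
  ~8%. The jitter stream is keyed by (seed, tumor) so paired libraries from
  one tumor share their targets.
- Counts are a single multinomial draw at `depth` (default 5×10⁶), so bulk
  totals equal the requested depth exactly.

### Demultiplexing posteriors

Pools must partition the cohort's samples (default: two halves, mirroring a
two-pools-of-four design). For a singlet, the hash posterior mass on the
true sample is logit-normal with location 0.999·a + 0.25·(1−a) and spread
0.1 + 1.5·(1−a) for adhesion a — concentrated near 1 at full adhesion,
diffuse at low adhesion — with the remainder spread Dirichlet over the other
samples and a small multiplet share. Genetic posteriors are
near-deterministic (Beta(800, 1) on the true sample). A `doublet_rate`
fraction of cells is re-labeled multiplet and receives Beta(60, 3) multiplet
mass in both tables. Rows are normalized to sum exactly to 1.

## Pseudo-bulk simulation

Per scenario draw: target proportions (realistic = observed; even = uniform
over the source's types; sparse = flat Dirichlet over the five common types;
weighted = epithelial exactly 0.70 plus a flat Dirichlet split of the rest),
then additive Gaussian noise (sd default 0.01) clamped at zero and
renormalized, then largest-remainder integerization to `n_cells` (default
2000; the apportionment sums exactly, making read conservation testable),
then per-type sampling with replacement and summation of raw counts. Ground
truth is the read share per type of the drawn cells; mRNA scaling factors
are deliberately not applied, preserving integer counts. The per-draw
sampling log is retained so the truth can be recomputed bit-for-bit.

The noise model (Gaussian, clamp, renormalize) and the flat-Dirichlet sparse
split are this package's choices where only "a random noise parameter" and a
support are externally specified; both are surfaced in `ScenarioConfig`.

## Reference profiles

Downsampling mirrors the full dataset's type proportions via
largest-remainder quotas, raises any zero quota for a represented type to
one by stealing a cell from the largest quota (keeping the total near
target), and draws without replacement within type. Ladder sizes (default
2000/1000/500/200) are drawn independently, not nested — the independent
reading of per-size simulation. Subsetting by demultiplexing labels keeps
exactly the sample-assigned cells.

## Demultiplexing calls

A cell whose multiplet class holds the maximum posterior is a multiplet
regardless of threshold (multiplets are never rescued as singlets — a simple
monotone rule, since the upstream caller's internals are unpublished);
otherwise the best sample is called iff its posterior ≥ threshold, ties
broken by lexicographically smallest sample id. Percentages are rounded
half-away-from-zero to one decimal, the printed convention. Concordance is
computed only over cells assigned to a sample by both modalities; with no
such cells the percentage is reported unavailable rather than 0 or 100.

## Deconvolution

Signatures average CPM-normalized cells within type (per-cell normalization
so large cells do not dominate the mean); all-zero genes are dropped. The
NNLS solver is a Lawson–Hanson active set with KKT tolerance 1e-10 and an
outer-iteration cap of 3× the column count. Both signature and bulk are CPM
(10⁶) normalized before solving — NNLS operates on linear mixtures, so log
transforms are avoided; CPM is the adopted and configurable normalization.
Coefficients are clamped at zero and renormalized to RNA fractions; no
mRNA-content back-correction is applied, matching the RNA-fraction truth
convention. External methods register with a minimum-cells-per-type
capability; types below it are excluded with an explicit reason, never
silently zeroed.

## Evaluation

- **RMSE**: per sample over cell types, then averaged over samples within a
  group — the per-sample-first nesting matches how average error is usually
  displayed per scenario panel.
- **Differences**: signed estimate − truth kept per observation; within any
  sample they sum to zero by the simplex constraint.
- **Robustness**: unbiased (n−1) sample variance across the varied axis per
  (method, sample, cell type); singleton keys are excluded with a warning.
  Stepwise mode recomputes cumulatively as each smaller reference joins.
- **Summary**: per method, (mean variance across bulk types, mean RMSE). The
  variance table is averaged over all its keys (samples and cell types
  together); averaging over cell types first gives the same value whenever
  the key set is balanced, and the output table retains the full variance
  table so either order can be recomputed.
- **ANOVA**: fixed-effects OLS with sequential (Type I) sums of squares in
  the configured factor order — default (method, enrichment, reference_size,
  dissociated); the analysis is restricted to a single cell type's fraction
  (epithelial, the most variable) because fractions sum to 1 and are not
  independent responses. Single-level factors are dropped with a warning; a
  zero-variance response yields a degenerate all-zero table instead of NaNs.

## What the synthetic benchmark shows — and does not

The generator plants exactly the biases it is calibrated to: fragile-type
loss, stress induction, histone/mito enrichment effects, adhesion-dependent
hash assignment. Passing tests therefore demonstrate that the pipeline's
estimators *detect and quantify planted effects correctly* — e.g. that the
ANOVA attributes epithelial-estimate variation to enrichment chemistry when
that is the planted driver. They do not establish performance on real
tumors: real data add ambient RNA, UMI collisions, doublet expression
profiles, annotation error, per-gene protocol effects beyond the modeled
blocks, and cell types absent from any reference. Magnitudes of
dissociation-driven over-representation of endothelial/fibroblast cells are
left configurable with neutral defaults, since only their direction is
externally established.

## Problem sizes and numerics

Default desk-scale sizes: 8 tumors × 2000 cells × 1200 genes; bulk depth
5×10⁶; 50 pseudo-bulk samples × 2000 cells per scenario and source. The test
suite and the calibration script run in well under a minute each at these
sizes. Compositions validate to 1 within 1e-9 (1e-6 for user input);
posterior rows within 1e-6; NNLS KKT within 1e-10; TSV floats are written at
6 significant digits for byte-stable reruns.
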