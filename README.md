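# deconvbench

Benchmarking bulk-tumor deconvolution under experimental-protocol variation.

Bulk RNA-seq deconvolution estimates the cell-type composition of a tissue
from its aggregate expression profile, using annotated single-cell data as a
reference. In practice the answer depends not only on the method but on how
the data were made: whether the tissue was dissociated before sequencing
(lysing erythrocytes, destroying adipocytes, inducing stress-response genes),
which mRNA enrichment chemistry was used (poly-A capture misses
non-polyadenylated canonical histone transcripts; rRNA depletion off-target
depletes mitochondrial RNA), and how large and how complete the single-cell
reference profile is. `deconvbench` is a framework for measuring how much
each of these factors moves a deconvolution result, aimed at computational
biologists choosing or building deconvolution pipelines for tumor data.

It provides:

- **a synthetic cohort generator** — virtual high-grade serous ovarian
  carcinoma (HGSOC) tumors with ~10 cell types (including fragile ones),
  gamma–Poisson single-cell counts, matched bulk libraries under three
  protocols (`rRNA_chunk`, `rRNA_dissociated`, `polyA_dissociated`) with
  calibrated protocol biases, and paired hash/genetic demultiplexing
  posterior tables;
- **a pseudo-bulk engine** — four composition scenarios (realistic / even /
  sparse / weighted), Gaussian proportion noise, integer cell sampling with
  replacement, and ground truth recorded as the fraction of *RNA reads*
  contributed by each cell type (not the cell-count fraction);
- **reference-profile manipulation** — composition-matched downsampling with
  a minimum of one cell per type, and subsetting by demultiplexing calls;
- **demultiplexing analysis** — posterior-threshold calling (0.90 / 0.85 /
  0.80), rate summaries at printed precision, cross-modality confusion
  matrices;
- **deconvolution** — a built-in non-negative least squares (NNLS) baseline
  on CPM-normalized data, solved by a Lawson–Hanson active-set
  implementation, plus a registry for plugging in external methods;
- **evaluation** — per-sample RMSE against RNA-fraction truth, signed
  estimate−truth differences per cell type, robustness as the unbiased
  variance of estimates across protocols or reference profiles, an
  accuracy-vs-robustness summary per method, and a sequential-SS fixed-effects
  ANOVA attributing variation in the most variable cell type's estimates to
  the experimental factors.

## Model

A bulk profile $b \in \mathbb{R}^G_{\ge 0}$ is treated as a non-negative
mixture of cell-type signatures $S \in \mathbb{R}^{G \times K}_{\ge 0}$
(mean CPM expression per type):

$$\hat{x} = \arg\min_{x \ge 0} \lVert S x - b \rVert_2, \qquad
\hat{p}_k = \hat{x}_k \Big/ \textstyle\sum_j \hat{x}_j .$$

Estimates $\hat p$ are RNA fractions — shares of total mRNA, not of cell
count — and are scored against the same convention: the pseudo-bulk ground
truth is the share of reads contributed by each type's sampled cells.

## Worked example

```python
import deconvbench as db

report = db.run_pipeline({
    "seed": 1,
    "cohort": {"n_tumors": 4, "cells_per_tumor": 500, "n_genes": 800},
    "bulk": {"depth": 1_000_000},
    "pseudobulk": {"scenarios": ["realistic", "even", "sparse", "weighted"],
                   "n_cells": 1000, "n_samples": 10},
    "reference_ladder": [1000, 500, 200],
})
print(report.rmse)
print(report.summary)
print(report.anova)
```

prints

```
method  scenario     rmse
  nnls      even 0.042470
  nnls realistic 0.034727
  nnls    sparse 0.035604
  nnls  weighted 0.031870

method  mean_variance  mean_rmse
  nnls       0.000779   0.036168

        factor   df   sum_sq         F        p  degenerate
    enrichment  1.0 0.016738 12.259766 0.001111       False
reference_size  3.0 0.002123  0.518323 0.671965       False
   dissociated  1.0 0.000499  0.365518 0.548710       False
      Residual 42.0 0.057340       NaN      NaN       False
```

Reading it: NNLS recovers pseudo-bulk compositions to an average RMSE of
0.03–0.04 across scenarios; its estimates vary across the three bulk
protocols with mean variance ~8×10⁻⁴; and of the experimental factors, the
mRNA enrichment chemistry has a significant effect on the epithelial-fraction
estimate (F ≈ 12, p ≈ 0.001) while reference-profile size and dissociation
status do not — entirely driven here by the simulated protocol biases, since
the generator plants them and nothing else. (The `method` factor is dropped
from this run's ANOVA because only one method was benchmarked.)

The same stages are scriptable from a shell:

```bash
deconvbench simulate reference --seed 1 --out out/ref
deconvbench pseudobulk --reference out/ref --scenario weighted --seed 1 --out out/pb
deconvbench run --seed 1 --out out/full
```

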