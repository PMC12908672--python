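# Methods

## Overview

scDDI addresses the dropout problem in single-cell RNA-seq count
matrices: a large share of zeros in a gene × cell matrix are technical
(the transcript was present but not captured) rather than biological
(the gene was silent). The package (i) estimates, for every entry, the
posterior probability that it is a dropout, (ii) builds a dropout-aware
similarity between cells, and (iii) replaces dropout-flagged entries
with predictions from a per-cell regression tree trained on the cell's
nearest neighbors. A group-structured count simulator with controllable
dropout provides ground truth for validation.

## Dropout model

For one gene, the observed counts across cells are modelled as a
two-component mixture

    f(y_j) = pi_j · Pois(y_j; lambda_j) + (1 − pi_j) · NB(y_j; mu_j, phi),

where the Poisson component (small mean) generates dropout events and
the negative binomial captures genuine expression with gene-level
dispersion phi (Var = mu + mu²/phi). Library-size variation is absorbed
through generalized linear links on the centered log library size
x_j = log L_j − mean(log L):

    logit(pi_j) = a0 + a1·x_j,   log(lambda_j) = b0 + b1·x_j,
    log(mu_j)   = c0 + c1·x_j,   phi shared within the gene.

The logit link is the canonical choice for a probability; the centering
is a pure reparameterization kept for numerical stability (the centering
constant is stored on the fit).

Estimation is by EM. The E-step computes responsibilities (the dropout
posterior); the M-step performs one damped Newton (or Fisher-scoring)
update for each of the three 2-parameter GLMs and one Newton update of
log phi, each with per-gene backtracking so that its expected complete
log-likelihood never decreases. By the usual EM argument the
observed-data log-likelihood is then non-decreasing across iterations;
this is asserted in the test suite to 1e-8 slack. Iteration stops when
the relative log-likelihood change falls below 1e-6 (default) or after
200 iterations.

Initialization is deterministic: pi from the gene's zero fraction
(clamped to [0.05, 0.95]), lambda = 0.1, mu and phi by method of moments
on the nonzero counts. Guards: per-cell pi is clamped to
[1e-6, 1 − 1e-6] and phi to [1e-3, 1e6]. Genes with constant counts
carry no mixture information; they are flagged as failed, excluded from
EM, and fall back to probability 1 at zeros and 0 elsewhere. Fits are
per-gene independent — the batched implementation vectorizes across
genes but every update uses only that gene's row, so results are
identical to fitting genes one at a time in any order.

The fit operates on raw integer counts (post-QC, restricted to the
selected highly variable genes): the mixture is a count model, and
library-size variation is handled by the GLM covariate rather than by
pre-normalization. The normalized matrix is used only downstream
(similarity and imputation).

Entries with posterior d > tau (default 0.5) are called dropouts and
become imputation targets regardless of their observed value; in
practice essentially all calls sit at observed zeros.

A known identifiability limit, visible in the simulations: for genes
with low expression, a zero from the biological component is
statistically indistinguishable from a dropout zero, and the maximum
likelihood solution attributes most zeros to the dropout spike. Under
uniform random masking of nonzero entries, detection recall is therefore
near 1 while precision is bounded by the fraction of observed zeros
that are truly masked. This ceiling shapes the threshold-sensitivity
results reported by the test suite.

### Logistic surrogate (ablation)

The ablation variant replaces the mixture by a single logistic curve of
zero probability against log2 gene mean, fitted by least squares to the
gene-mean/zero-fraction relationship and applied only at observed zeros.
It is a surrogate for the family of mean–dropout curves used by several
imputation tools, deliberately simple, and exists only to quantify the
contribution of the mixture model.

## Weighted cosine similarity

Cells are compared on the normalized HVG matrix with per-gene weights
driven by dropout status:

    s_ij = Σ_g w_g y_gi y_gj / sqrt(Σ_g w_g y_gi²) sqrt(Σ_g w_g y_gj²),

with w_g = 1 when the two cells' dropout calls for gene g agree and
w_g = (gene g's dropout rate) when they disagree. A dropout in a gene
that rarely drops out is strong evidence the cells differ, so discordant
low-rate genes are down-weighted least severely in the norms — the entry
is "questionable" and contributes little. Observed values are used as-is
inside the formula (dropout-called entries are not zeroed or excluded).

The full matrix is computed with Gram-product algebra (the pairwise
weight matrix decomposes into rank-one status interactions), making the
all-pairs computation a handful of BLAS calls; the pairwise reference
implementation is retained and the two are tested for entrywise
agreement. Cells with a zero weighted norm receive similarity 0
everywhere and are ineligible for imputation.

Neighbor selection applies a global cutoff at the sim.cut percentile
(default 75th) of the off-diagonal similarity distribution, then keeps
per cell the top k = 20 (default) most similar cells above it. Cells
with fewer than 3 qualifying neighbors fall back to their overall top 3
and are flagged. k should be set near the smallest expected
subpopulation size; it is exposed on the CLI.

## Regression-tree imputation

For a target cell, genes not called dropout form the training sample:
each gene contributes a row whose features are its normalized expression
across the cell's neighbors (columns ordered by descending similarity)
and whose response is the target cell's observed value. A CART
regression tree (variance-reduction splitting; max depth 15, min
samples per leaf 10 by default) is fitted per cell and predicts the
cell's dropout-called genes from the same features. Predictions are
clamped at zero. Similarity scores order and gate the neighbors but are
not regression features — a per-neighbor scalar is constant across the
gene-samples and carries no split information.

Neighbor entries that are themselves dropout-called are used as
observed: imputation is single-pass, with no recursive refinement, so
the result is independent of cell processing order and fully
deterministic given the seed. Cells whose training table is too small
(< 10 genes) fall back to the unweighted neighbor mean for each target
gene; cells with too few neighbors are left unimputed and reported.
An optional grid search (depth {5,10,15,20} × leaf {5,10,20}, five-fold
cross-validated RMSE, ties to the simpler model) can replace the fixed
hyperparameters; it is off by default for speed and reproducibility, and
the per-cell Spearman CV score is recorded only when requested.

Mean imputation (the ablation variant) replaces the tree by the
unweighted mean of the neighbors' values for each target gene.

## Preprocessing

Quality control keeps cells expressing more than 1000 genes, then genes
whose count exceeds 5 in at least 5% of the cells in which they are
expressed (the denominator is expressing cells, read literally; genes
expressed nowhere are dropped). The filter runs once, cells before
genes, with no iteration to a fixed point. Normalization scales each
cell to the median library size and applies log2(x+1), which preserves
zeros exactly and is monotone within each cell; the normalizer is
pluggable because the downstream stages only require a monotone,
zero-preserving transform, and users of dedicated normalization methods
can supply their own matrix. The top 1000 genes by dispersion
(variance/mean, z-scored within up to 20 equal-frequency mean bins,
ties broken by gene index) are retained for all downstream stages.

## Simulator

The generator emulates the Splat group-structured model: gamma gene
means (shape 0.6, rate 0.3), per-group log-normal DE factors (location
0.1, scale 0.4, down-regulated with probability 1/2) applied to a
configurable fraction of genes per group, log-normal library sizes
(location 11, scale 0.2 on the natural-log scale), a
biological-coefficient-of-variation stage
(BCV = (0.1 + 1/sqrt(mean)) scaled by a per-gene inverse-chi-square
factor with 60 degrees of freedom) and Gamma–Poisson sampling. These
are the Splat defaults; the BCV stage is retained because without it
counts are equidispersed and the NB component of the dropout mixture is
degenerate (phi pinned at its guard). Outlier genes are disabled.
Group labels follow largest-remainder rounding, so requested proportions
are matched exactly. Presets mirror seven published group/DE/size
configurations (dataset1 ... dataset7).

Controlled dropout zeroes an exact count — round(rate × nnz) — of
uniformly chosen nonzero entries (Bernoulli masking would make the
stated rates only approximate), recording the mask for scoring; the
same mechanism masks 5% of nonzero entries of arbitrary matrices for
real-data recovery experiments.

What the generator does not emulate: outlier genes, batch effects,
trajectory/path structure, expression-dependent (logistic) dropout, and
any form of gene–gene co-regulation beyond the shared group factors.
Consequences: recovery experiments here corrupt entries uniformly at
random, which is harsher than expression-dependent dropout for
well-expressed genes; passing tests demonstrate correct mechanics and
calibrated behavior under the stated generative model, not performance
on any particular real dataset.

## Evaluation

Clustering uses PCA (50 components) on the cell × gene matrix, a
cosine-metric kNN graph (15 neighbors) and Leiden community detection
(resolution 1.0), deterministic given the seed; Leiden is the default
backend for determinism, with the understanding that Louvain-family
algorithms give closely comparable partitions. Agreement with true
labels is scored by ARI and NMI (arithmetic-mean normalization).
Recovery is scored on masked entries only (Pearson, Spearman, RMSE,
MAE) on the log2-normalized scale; because uniform masking roughly
preserves relative library sizes, the corrupted-data normalization and
the truth normalization share a common scale. Detection metrics
(precision/recall/F1) compare calls at each threshold in 0.3..0.8
against the planted mask over all matrix entries, so calls at genuinely
biological zeros count as false positives. Paired method comparisons
use the two-sided Wilcoxon signed-rank test (exact null for n ≤ 25,
normal approximation with continuity correction beyond) and t-based
95% confidence intervals.

## Problem sizes and replication

The simulation benchmarks run at the Dataset 1 scale (5000 genes × 500
cells): recovery experiments average five seeded replicates per dropout
rate, and clustering/ablation comparisons use ten seeded replicates.
All replicate seeds derive from one master seed through a
SeedSequence-spawn scheme, so every reported number is reproducible
from a single integer.

In the recovery benchmark the QC stage is disabled: simulated matrices
contain no low-quality cells by construction, and at high controlled
dropout (≥ 60–80%) the >1000-expressed-genes cell filter — calibrated
for transcriptome-wide real data — would otherwise discard every
corrupted cell and make the masked entries unscorable. The clustering
benchmark, which adds no artificial dropout, runs the full default QC.

## Known limitations

- Detection precision under uniform masking is capped by the
  biological-zero/dropout confusion described above; the mixture cannot
  beat that information-theoretic ceiling at low expression.
- The per-cell tree is trained on at most a few thousand gene-samples
  with k ≈ 20 features; in very sparse cells the training table shrinks
  and the mean fallback engages.
- Similarity percentile cutoffs are global; in datasets dominated by one
  large population, rare-population cells may rely on the top-3
  fallback.
- The simulator's parameters are stand-ins for the published generative
  model's defaults; absolute benchmark values depend on them, while the
  qualitative orderings (imputed vs raw, full model vs ablations) are
  the stable claims.
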