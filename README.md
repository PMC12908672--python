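# scDDI — single-cell dropout detection and imputation

scDDI recovers gene expression lost to *dropout* in single-cell RNA-seq
count matrices. Dropout — failed transcript capture — fills the gene ×
cell matrix with technical zeros that are easily confused with genuine
non-expression, degrading clustering, marker detection and any analysis
downstream. scDDI is aimed at analysts who want an interpretable,
statistically explicit alternative to smoothing- or deep-learning-based
imputation.

The method has three stages:

1. **Dropout detection.** Each gene's counts y_j across cells follow a
   Poisson–negative binomial mixture
   f(y_j) = π_j·Pois(y_j; λ_j) + (1−π_j)·NB(y_j; μ_j, φ), where the
   low-mean Poisson component generates dropouts. π_j, λ_j and μ_j are
   tied to the cell's library size through log-linear/logit GLM links
   and estimated per gene by EM. The dropout posterior
   d_j = π̂_j f̂_Pois / (π̂_j f̂_Pois + (1−π̂_j) f̂_NB)
   is thresholded at τ = 0.5 to flag entries for imputation.
2. **Dropout-aware similarity.** Cells are compared by a weighted
   cosine similarity s_ij = Σ w_g y_gi y_gj / (‖y_i‖_w ‖y_j‖_w) whose
   gene weights w_g equal 1 when the two cells' dropout statuses agree
   and the gene's dropout rate when they disagree. Per cell, the top
   k = 20 neighbors above the 75th-percentile similarity cutoff are
   kept.
3. **Regression-tree imputation.** For each cell, a CART regression
   tree (depth ≤ 15, ≥ 10 samples per leaf) is trained on the cell's
   non-dropout genes — features are the genes' expression across the
   cell's neighbors — and predicts the cell's dropout-flagged genes.
   Entries not flagged are never modified.

The package also ships a Splat-style group-structured count simulator
with exact-count controlled dropout, and an evaluation battery (ARI/NMI
clustering agreement, masked-entry recovery, detection
precision/recall/F1, paired signed-rank comparisons). See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
import scddi

# simulate two groups with known truth, then corrupt 40% of nonzeros
truth = scddi.simulate_groups(n_genes=1000, n_cells=200,
                              group_props=(0.6, 0.4), de_props=(0.3, 0.3),
                              seed=0)
sim = scddi.apply_random_dropout(truth, rate=0.4, seed=1)

# run detection -> similarity -> imputation (QC off: simulated data)
cfg = scddi.RunConfig(apply_qc=False, n_hvg=500, seed=0)
res = scddi.run_imputation(sim.observed_matrix(), cfg)

# score recovery on the masked entries (log2-normalized scale)
import pandas as pd
gene_pos = pd.Index(sim.true_matrix().gene_ids).get_indexer(res.normalized.gene_ids)
truth_norm = scddi.normalize_log(sim.true_matrix()).values[gene_pos]
mask = sim.dropout_mask[gene_pos]
print({k: round(v, 4) for k, v in
       scddi.recovery_scores(res.imputation.values, truth_norm, mask).items()})
print("entries imputed:", int(res.imputation.imputed_mask.sum()))
```

```
{'pearson': 0.8396, 'spearman': 0.8479, 'rmse': 1.1254, 'mae': 0.807}
entries imputed: 47978
```

The Pearson/Spearman values measure how well the imputed values track
the (normalized) true expression at exactly the entries that were
artificially zeroed; RMSE/MAE are the corresponding reconstruction
errors on the log2 scale. The imputed-entry count shows that the
detector flagged (essentially) the observed zeros of the 500 most
variable genes.

The same pipeline is available from the shell:

```bash
scddi simulate --preset dataset1 --dropout-rate 0.4 --seed 1 --output-dir sim_out
scddi impute --input sim_out/observed_counts.csv --no-qc --seed 1 --output-dir run_out
scddi evaluate --truth sim_out/true_counts.csv --imputed run_out/imputed.csv \
               --mask sim_out/dropout_mask.csv
scddi benchmark --preset dataset1 --seed 0 --seed 1 --seed 2
```

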