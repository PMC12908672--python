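"""Splat-style synthetic scRNA-seq counts with known ground truth.

The generator follows the classic group-structured generative chain:
gamma-distributed gene means, per-group log-normal differential
expression factors applied to a configurable fraction of genes,
log-normal library sizes, expected expression proportional to
(gene mean x group factor) scaled to each cell's library size, and
Poisson sampling.  Outlier genes are disabled (out_prob = 0).  Group
labels are assigned by largest-remainder rounding, so requested
proportions are matched exactly.

Controlled dropout is applied afterwards by zeroing an exact count of
uniformly chosen nonzero entries, recording the mask as ground truth for
recovery and detection experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io_preprocess import CountMatrix

#: Table of simulation presets: (group proportions, per-group DE gene
#: fractions, n_genes, n_cells).
PRESETS = {
    "dataset1": ((0.8, 0.1, 0.1), (0.6, 0.2, 0.2), 5000, 500),
    "dataset2": ((0.6, 0.2, 0.1, 0.1), (0.5, 0.2, 0.2, 0.1), 8000, 800),
    "dataset3": ((0.6, 0.2, 0.2), (0.6, 0.3, 0.1), 6000, 400),
    "dataset4": ((0.7, 0.2, 0.1), (0.7, 0.2, 0.1), 10000, 600),
    "dataset5": ((0.8, 0.1, 0.1), (0.5, 0.3, 0.2), 6000, 2000),
    "dataset6": ((0.5, 0.2, 0.2, 0.1), (0.4, 0.2, 0.2, 0.2), 10000, 5000),
    "dataset7": ((0.6, 0.2, 0.2), (0.6, 0.2, 0.2), 8000, 2000),
}


@dataclass
class SimTruth:
    """Simulated truth: clean counts, corrupted counts, mask, labels."""

    true_counts: np.ndarray
    observed_counts: np.ndarray
    dropout_mask: np.ndarray
    group_labels: np.ndarray
    de_factors: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def n_genes(self) -> int:
        return self.true_counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.true_counts.shape[1]

    def observed_matrix(self) -> CountMatrix:
        g = np.array([f"gene{i}" for i in range(self.n_genes)], dtype=object)
        c = np.array([f"cell{j}" for j in range(self.n_cells)], dtype=object)
        return CountMatrix(self.observed_counts, g, c)

    def true_matrix(self) -> CountMatrix:
        g = np.array([f"gene{i}" for i in range(self.n_genes)], dtype=object)
        c = np.array([f"cell{j}" for j in range(self.n_cells)], dtype=object)
        return CountMatrix(self.true_counts, g, c)


def _largest_remainder(props, n: int) -> np.ndarray:
    """Integer group sizes matching proportions exactly to n."""
    raw = np.asarray(props, dtype=np.float64) * n
    base = np.floor(raw).astype(np.int64)
    rem = n - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    base[order[:rem]] += 1
    return base


def simulate_groups(
    n_genes: int,
    n_cells: int,
    group_props,
    de_props,
    mean_shape: float = 0.6,
    mean_rate: float = 0.3,
    de_fac_loc: float = 0.1,
    de_fac_scale: float = 0.4,
    lib_loc: float = 11.0,
    lib_scale: float = 0.2,
    bcv_common: float = 0.1,
    bcv_df: float = 60.0,
    out_prob: float = 0.0,
    seed: int = 0,
) -> SimTruth:
    """Simulate group-structured counts.

    ``de_props[k]`` is the fraction of genes differentially expressed in
    group k; their multiplicative factors are log-normal
    (location ``de_fac_loc``, scale ``de_fac_scale``) with a random sign
    on the log scale (up- or down-regulation with equal probability).

    Biological noise follows the Splat biological-coefficient-of-variation
    stage: per entry, BCV = (bcv_common + 1/sqrt(mean)) scaled by a
    per-gene inverse-chi-square factor with ``bcv_df`` degrees of freedom,
    and counts are Gamma–Poisson with that coefficient of variation.
    Setting ``bcv_common=0`` and ``bcv_df=inf`` recovers pure Poisson
    sampling.
    """
    group_props = np.asarray(group_props, dtype=np.float64)
    de_props = np.asarray(de_props, dtype=np.float64)
    if abs(group_props.sum() - 1.0) > 1e-9:
        raise ValueError("group proportions must sum to 1")
    if len(de_props) != len(group_props):
        raise ValueError("de_props must have one entry per group")
    if out_prob != 0.0:
        raise NotImplementedError("outlier genes are disabled (out_prob=0)")
    rng = np.random.default_rng(seed)
    r_means, r_de, r_lib, r_counts = rng.spawn(4)
    n_groups = len(group_props)

    gene_means = r_means.gamma(shape=mean_shape, scale=1.0 / mean_rate,
                               size=n_genes)
    gene_means = np.maximum(gene_means, 1e-8)

    de_factors = np.ones((n_genes, n_groups))
    for k in range(n_groups):
        n_de = int(round(de_props[k] * n_genes))
        idx = r_de.choice(n_genes, size=n_de, replace=False)
        mag = r_de.lognormal(mean=de_fac_loc, sigma=de_fac_scale, size=n_de)
        down = r_de.random(n_de) < 0.5
        de_factors[idx, k] = np.where(down, 1.0 / mag, mag)

    sizes = _largest_remainder(group_props, n_cells)
    labels = np.repeat(np.arange(n_groups), sizes)

    lib = r_lib.lognormal(mean=lib_loc, sigma=lib_scale, size=n_cells)

    group_means = gene_means[:, None] * de_factors      # genes x groups
    col_tot = group_means.sum(axis=0)
    expected = group_means[:, labels] / col_tot[labels][None, :] * lib[None, :]
    if bcv_common > 0 and np.isfinite(bcv_df):
        gene_scale = np.sqrt(bcv_df / r_counts.chisquare(bcv_df, size=n_genes))
        bcv = (bcv_common + 1.0 / np.sqrt(np.maximum(expected, 1e-12)))
        bcv = bcv * gene_scale[:, None]
        shape = 1.0 / (bcv * bcv)
        noisy = r_counts.gamma(shape=shape, scale=expected / shape)
        true_counts = r_counts.poisson(noisy).astype(np.int64)
    else:
        true_counts = r_counts.poisson(expected).astype(np.int64)

    params = {
        "n_genes": n_genes, "n_cells": n_cells,
        "group_props": [float(p) for p in group_props],
        "de_props": [float(p) for p in de_props],
        "mean_shape": mean_shape, "mean_rate": mean_rate,
        "de_fac_loc": de_fac_loc, "de_fac_scale": de_fac_scale,
        "lib_loc": lib_loc, "lib_scale": lib_scale,
        "bcv_common": bcv_common, "bcv_df": bcv_df,
        "out_prob": out_prob, "seed": int(seed),
    }
    return SimTruth(
        true_counts=true_counts,
        observed_counts=true_counts.copy(),
        dropout_mask=np.zeros_like(true_counts, dtype=bool),
        group_labels=labels,
        de_factors=de_factors,
        params=params,
    )


def simulate_preset(preset: str, seed: int = 0, **overrides) -> SimTruth:
    """Simulate one of the named preset configurations."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; options: {sorted(PRESETS)}")
    props, de, g, c = PRESETS[preset]
    kwargs = dict(n_genes=g, n_cells=c, group_props=props, de_props=de,
                  seed=seed)
    kwargs.update(overrides)
    truth = simulate_groups(**kwargs)
    truth.params["preset"] = preset
    return truth


def apply_random_dropout(truth: SimTruth, rate: float, seed: int = 0) -> SimTruth:
    """Zero exactly round(rate x nnz) uniformly chosen nonzero entries.

    Operates on the *true* counts; returns a new SimTruth whose observed
    counts carry the corruption and whose mask records it.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("dropout rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    nz = np.argwhere(truth.true_counts > 0)
    n_mask = int(round(rate * len(nz)))
    chosen = rng.choice(len(nz), size=n_mask, replace=False)
    mask = np.zeros_like(truth.true_counts, dtype=bool)
    mask[nz[chosen, 0], nz[chosen, 1]] = True
    observed = truth.true_counts.copy()
    observed[mask] = 0
    params = dict(truth.params)
    params.update({"dropout_rate": float(rate), "dropout_seed": int(seed)})
    return SimTruth(
        true_counts=truth.true_counts,
        observed_counts=observed,
        dropout_mask=mask,
        group_labels=truth.group_labels,
        de_factors=truth.de_factors,
        params=params,
    )


def mask_nonzero_fraction(E: CountMatrix, frac: float = 0.05, seed: int = 0):
    """Mask an exact fraction of nonzero entries of an arbitrary matrix.

    Returns ``(masked CountMatrix, boolean mask)`` for recovery scoring.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie strictly between 0 and 1")
    nz = np.argwhere(E.values > 0)
    if len(nz) == 0:
        raise ValueError("matrix has no nonzero entries to mask")
    rng = np.random.default_rng(seed)
    n_mask = int(round(frac * len(nz)))
    chosen = rng.choice(len(nz), size=n_mask, replace=False)
    mask = np.zeros_like(E.values, dtype=bool)
    mask[nz[chosen, 0], nz[chosen, 1]] = True
    vals = E.values.copy()
    vals[mask] = 0
    return CountMatrix(vals, E.gene_ids, E.cell_ids), mask


def write_simtruth(truth: SimTruth, outdir) -> None:
    """Export counts, mask, labels (CSV) and parameters (YAML)."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = [f"gene{i}" for i in range(truth.n_genes)]
    c = [f"cell{j}" for j in range(truth.n_cells)]
    pd.DataFrame(truth.true_counts, index=g, columns=c).to_csv(
        outdir / "true_counts.csv")
    pd.DataFrame(truth.observed_counts, index=g, columns=c).to_csv(
        outdir / "observed_counts.csv")
    pd.DataFrame(truth.dropout_mask.astype(int), index=g, columns=c).to_csv(
        outdir / "dropout_mask.csv")
    pd.Series(truth.group_labels, index=c, name="group").to_csv(
        outdir / "group_labels.csv")
    with open(outdir / "params.yaml", "w") as fh:
        yaml.safe_dump(truth.params, fh)
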