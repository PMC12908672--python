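"""Dropout-aware weighted cosine similarity (WCS) between cells.

For cells i and j over p genes the similarity is

    s_ij = sum_g w_g y_gi y_gj /
           ( sqrt(sum_g w_g y_gi^2) * sqrt(sum_g w_g y_gj^2) ),

where w_g = 1 when the two cells' dropout statuses for gene g agree
(both called dropout, or both not), and w_g = the gene's dropout rate
when they disagree.  Genes with low dropout rates are thus down-weighted
exactly when the pair is discordant for them, so that a dropout in a
gene that rarely drops out pulls the pair apart more than one in a gene
that drops out everywhere.

Neighbor selection applies a global percentile cutoff (sim.cut, default
the 75th percentile of the off-diagonal similarity distribution) and
keeps, per cell, the top-k most similar cells above it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GeneDropoutRates:
    """Per-gene fraction of cells called dropout at the current threshold."""

    rate: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rate, dtype=np.float64)
        if r.size and (r.min() < 0 or r.max() > 1):
            raise ValueError("dropout rates must lie in [0, 1]")
        self.rate = r


@dataclass
class SimilarityMatrix:
    values: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        self.values = v

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]


@dataclass
class NeighborSet:
    """Per-cell neighbor lists sorted by descending similarity."""

    cutoff_percentile: float
    cutoff_value: float
    k: int
    neighbors: list  # per cell: list of (neighbor index, similarity)
    fallback: np.ndarray  # per-cell flag: percentile cutoff was relaxed


def gene_dropout_rate(D) -> GeneDropoutRates:
    """Fraction of cells whose entry for each gene is called dropout."""
    return GeneDropoutRates(D.calls.mean(axis=1))


def wcs_pair(x, y, status_x, status_y, rates: GeneDropoutRates) -> float:
    """Weighted cosine similarity between two cell profiles (reference
    implementation; :func:`similarity_matrix` is the vectorized path)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    sx = np.asarray(status_x, dtype=bool)
    sy = np.asarray(status_y, dtype=bool)
    if not (len(x) == len(y) == len(sx) == len(sy) == len(rates.rate)):
        raise ValueError("profile, status and rate lengths must agree")
    w = np.where(sx == sy, 1.0, rates.rate)
    num = float(np.sum(w * (x * y)))
    nx = float(np.sum(w * x * x))
    ny = float(np.sum(w * y * y))
    if nx <= 0 or ny <= 0:
        warnings.warn("zero weighted norm; similarity defined as 0")
        return 0.0
    # single sqrt of the product keeps the function exactly symmetric
    return num / np.sqrt(nx * ny)


def similarity_matrix(En, D, mode: str = "wcs") -> SimilarityMatrix:
    """All-pairs cell similarity on the normalized matrix.

    ``mode="wcs"`` uses the dropout-aware weights; ``mode="cosine"`` is the
    ablation variant (all weights 1).  The diagonal is set to 1 and cells
    with a zero weighted norm get similarity 0 against everything.
    """
    X = np.asarray(En.values, dtype=np.float64)
    G, C = X.shape
    if mode == "cosine":
        norms = np.sqrt((X * X).sum(axis=0))
        safe = norms > 0
        Xn = np.where(safe[None, :], X / np.where(safe, norms, 1.0)[None, :], 0.0)
        S = Xn.T @ Xn
    elif mode == "wcs":
        if D.calls.shape != X.shape:
            raise ValueError(
                f"dropout matrix shape {D.calls.shape} does not match "
                f"expression shape {X.shape}"
            )
        r = gene_dropout_rate(D).rate
        St = D.calls.astype(np.float64)
        rp = (1.0 - r)[:, None]             # weight deficit on discordant genes
        Xs = X * St
        X2 = X * X
        # w_g(i,j) = 1 - (1-r_g) * xor(S_gi, S_gj); xor = s_i + s_j - 2 s_i s_j
        A = X.T @ X
        P = (rp * Xs).T @ X
        Num = A - P - P.T + 2.0 * (rp * Xs).T @ Xs
        q = X2.sum(axis=0)                  # unweighted squared norms
        u = (rp * St * X2).sum(axis=0)      # own-status deficit
        V = (rp * X2).T @ St                # V[i,j] = sum_g (1-r) X_gi^2 S_gj
        T = (rp * St * X2).T @ St
        Den_i = q[:, None] - u[:, None] - V + 2.0 * T   # ||x_i||_w^2 for pair (i,j)
        Den_i = np.maximum(Den_i, 0.0)
        den = np.sqrt(Den_i * Den_i.T)
        zero = den <= 1e-300
        if np.any(zero & ~np.eye(C, dtype=bool)):
            warnings.warn("cells with zero weighted norm; similarities set to 0")
        S = np.where(zero, 0.0, Num / np.where(zero, 1.0, den))
    else:
        raise ValueError(f"unknown similarity mode {mode!r}")
    S = np.clip(S, -1.0, 1.0)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, 1.0)
    # zero-profile cells: self-similarity is undefined; keep diagonal 1 only
    # for cells with a nonzero profile
    nonzero_profile = (X != 0).any(axis=0)
    for j in np.flatnonzero(~nonzero_profile):
        S[j, :] = 0.0
        S[:, j] = 0.0
    return SimilarityMatrix(S, getattr(En, "cell_ids", None))


def select_neighbors(
    S: SimilarityMatrix,
    sim_cut: float = 75.0,
    k: int = 20,
    min_neighbors: int = 3,
) -> NeighborSet:
    """Per-cell top-k neighbors above the global percentile cutoff.

    The cutoff is the ``sim_cut``-th percentile of all off-diagonal
    similarities.  Cells with fewer than ``min_neighbors`` qualifying
    neighbors fall back to their overall top ``min_neighbors`` and are
    flagged.
    """
    if not 0 <= sim_cut <= 100:
        raise ValueError("sim_cut must be a percentile in [0, 100]")
    if k < 1:
        raise ValueError("k must be >= 1")
    V = S.values
    C = V.shape[0]
    if C < 2:
        raise ValueError("need at least 2 cells to select neighbors")
    off = V[~np.eye(C, dtype=bool)]
    cutoff = float(np.percentile(off, sim_cut))
    neighbors = []
    fallback = np.zeros(C, dtype=bool)
    for j in range(C):
        sims = V[j].copy()
        sims[j] = -np.inf
        order = np.argsort(-sims, kind="stable")
        qualifying = [i for i in order if sims[i] >= cutoff][:k]
        if len(qualifying) < min_neighbors:
            fallback[j] = True
            qualifying = list(order[:min_neighbors])
        neighbors.append([(int(i), float(V[j, i])) for i in qualifying])
    return NeighborSet(
        cutoff_percentile=float(sim_cut),
        cutoff_value=cutoff,
        k=int(k),
        neighbors=neighbors,
        fallback=fallback,
    )


def write_similarity(S: SimilarityMatrix, nbrs: NeighborSet, outdir) -> None:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = S.cell_ids if S.cell_ids is not None else np.arange(S.n_cells)
    pd.DataFrame(S.values, index=ids, columns=ids).to_csv(
        outdir / "similarity.csv", float_format="%.6g")
    rows = []
    for j, lst in enumerate(nbrs.neighbors):
        for rank, (i, s) in enumerate(lst, start=1):
            rows.append({"cell": ids[j], "rank": rank, "neighbor": ids[i],
                         "similarity": s, "fallback": bool(nbrs.fallback[j])})
    pd.DataFrame(rows).to_csv(outdir / "neighbors.tsv", sep="\t", index=False)
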