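"""Reading, writing and preprocessing of gene × cell count matrices.

The pipeline operates on two in-memory containers: :class:`CountMatrix`
(raw nonnegative integer counts, genes as rows) and
:class:`NormalizedMatrix` (library-size-scaled, log2(x+1)-transformed
expression).  Preprocessing follows the usual single-cell recipe: quality
filters on cells and genes, median-library-size normalization with a
pseudocount of 1, and selection of the most highly variable genes by a
mean-binned dispersion statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class ValidationError(ValueError):
    """Raised when an input matrix violates a structural invariant."""


class EmptyResultError(ValueError):
    """Raised when a filter would remove every gene or every cell."""


def _check_ids(ids, what: str) -> np.ndarray:
    ids = np.asarray(ids, dtype=object)
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what} identifiers: {dupes[:5]}")
    return ids


@dataclass
class CountMatrix:
    """Raw gene × cell counts with identifiers and per-cell library sizes.

    ``library_sizes[j]`` is always the column sum of ``values`` for cell j;
    it is recomputed on construction and after any filtering.
    """

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    library_sizes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValidationError("count matrix must be 2-dimensional")
        if not np.issubdtype(v.dtype, np.integer):
            if not np.allclose(v, np.round(v), atol=0):
                bad = np.argwhere(v != np.round(v))[0]
                raise ValidationError(
                    f"non-integer count at (gene {bad[0]}, cell {bad[1]})"
                )
            v = v.astype(np.int64)
        if v.size and v.min() < 0:
            bad = np.argwhere(v < 0)[0]
            raise ValidationError(
                f"negative count at (gene {bad[0]}, cell {bad[1]})"
            )
        self.values = v
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if v.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError(
                f"shape {v.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        self.library_sizes = v.sum(axis=0).astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = slice(None) if gene_mask is None else np.asarray(gene_mask)
        cm = slice(None) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            self.values[gm][:, cm], self.gene_ids[gm], self.cell_ids[cm]
        )


@dataclass
class NormalizedMatrix:
    """Normalized log2-scale expression; zeros of the source stay zero."""

    values: np.ndarray
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    normalization_tag: str = "cpm_median"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValidationError("normalized matrix must be 2-dimensional")
        if v.size and v.min() < -1e-12:
            raise ValidationError("normalized values must be nonnegative")
        self.values = np.maximum(v, 0.0)
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.cell_ids = _check_ids(self.cell_ids, "cell")
        if v.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValidationError("shape does not match identifier lengths")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "NormalizedMatrix":
        gm = slice(None) if gene_mask is None else np.asarray(gene_mask)
        cm = slice(None) if cell_mask is None else np.asarray(cell_mask)
        return NormalizedMatrix(
            self.values[gm][:, cm],
            self.gene_ids[gm],
            self.cell_ids[cm],
            self.normalization_tag,
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_counts(path, format: str = "csv") -> CountMatrix:
    """Read a gene × cell count matrix.

    Parameters
    ----------
    path
        File path (csv/tsv) or directory (mtx_10x, containing ``matrix.mtx``
        plus ``genes.tsv``/``features.tsv`` and ``barcodes.tsv``).
    format
        One of ``mtx_10x``, ``csv``, ``tsv``.  For csv/tsv the header row
        holds cell ids and the first column holds gene ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_10x":
        mtx = path / "matrix.mtx"
        feats = path / "features.tsv"
        if not feats.exists():
            feats = path / "genes.tsv"
        barcodes = path / "barcodes.tsv"
        for f in (mtx, feats, barcodes):
            if not f.exists():
                raise FileNotFoundError(f)
        m = spio.mmread(str(mtx))
        values = np.asarray(m.todense() if sparse.issparse(m) else m)
        genes = pd.read_csv(feats, sep="\t", header=None).iloc[:, 0].to_numpy(object)
        cells = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].to_numpy(object)
        return CountMatrix(values, genes, cells)
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        vals = df.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = np.argwhere(~np.vectorize(np.isreal)(vals))
            coord = tuple(bad[0]) if len(bad) else ("?", "?")
            raise ValidationError(f"non-numeric entry at {coord}")
        return CountMatrix(vals, df.index.to_numpy(object), df.columns.to_numpy(object))
    raise ValueError(f"unknown format {format!r}")


def write_matrix(m, path, format: str = "csv") -> None:
    """Write a Count/NormalizedMatrix; inverse of :func:`read_counts`."""
    path = Path(path)
    if format == "mtx_10x":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(m.values))
        pd.Series(m.gene_ids).to_csv(path / "features.tsv", sep="\t",
                                     header=False, index=False)
        pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t",
                                     header=False, index=False)
        return
    if format in ("csv", "tsv"):
        df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.cell_ids)
        if np.issubdtype(np.asarray(m.values).dtype, np.integer):
            df.to_csv(path, sep="," if format == "csv" else "\t")
        else:
            df.to_csv(path, sep="," if format == "csv" else "\t",
                      float_format="%.12g")
        return
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# QC / normalization / HVG
# ---------------------------------------------------------------------------

def qc_filter(
    E: CountMatrix,
    min_genes_per_cell: int = 1000,
    min_count: int = 5,
    min_cell_frac: float = 0.05,
) -> CountMatrix:
    """Remove low-quality cells, then low-quality genes.

    A cell is kept if it expresses (count > 0) strictly more than
    ``min_genes_per_cell`` genes.  A gene is kept if, among the retained
    cells in which it is expressed, the fraction with count >
    ``min_count`` is at least ``min_cell_frac``.  Genes expressed in no
    cell are removed.  Library sizes are recomputed.
    """
    expressed = E.values > 0
    cell_mask = expressed.sum(axis=0) > min_genes_per_cell
    if not cell_mask.any():
        raise EmptyResultError(
            f"cell filter (> {min_genes_per_cell} expressed genes) "
            "removed all cells"
        )
    v = E.values[:, cell_mask]
    expr = v > 0
    n_expr = expr.sum(axis=1)
    n_high = (v > min_count).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_expr > 0, n_high / np.maximum(n_expr, 1), 0.0)
    gene_mask = (n_expr > 0) & (frac >= min_cell_frac)
    if not gene_mask.any():
        raise EmptyResultError(
            f"gene filter (count > {min_count} in >= {min_cell_frac:.0%} "
            "of expressing cells) removed all genes"
        )
    return E.subset(gene_mask, cell_mask)


def normalize_log(
    E: CountMatrix,
    method: str = "cpm_median",
    pseudocount: float = 1.0,
) -> NormalizedMatrix:
    """Scale each cell to the median library size and take log2(x + pc).

    With ``method="none"`` the counts are log-transformed without scaling.
    A pseudocount of 1 maps zeros to zero exactly.
    """
    if E.n_genes == 0 or E.n_cells == 0:
        raise EmptyResultError("cannot normalize an empty matrix")
    L = E.library_sizes.astype(np.float64)
    if method == "cpm_median":
        if (L == 0).any():
            j = int(np.flatnonzero(L == 0)[0])
            raise ValidationError(
                f"cell {E.cell_ids[j]!r} has zero library size; run qc_filter"
            )
        scaled = E.values * (np.median(L) / L)[None, :]
    elif method == "none":
        scaled = E.values.astype(np.float64)
    else:
        raise ValueError(f"unknown normalization {method!r}")
    return NormalizedMatrix(
        np.log2(scaled + pseudocount),
        E.gene_ids,
        E.cell_ids,
        normalization_tag=f"{method}+log2(x+{pseudocount:g})",
    )


def select_hvg(
    En: NormalizedMatrix, n_top: int = 1000, n_bins: int = 20
) -> NormalizedMatrix:
    """Keep the ``n_top`` genes with highest normalized dispersion.

    Dispersion = variance/mean on the normalized scale, z-scored within
    ``n_bins`` equal-frequency bins of the gene mean (the classic
    dispersion-based highly-variable-gene ranking).  Ties break on gene
    index so the selection is deterministic.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    G = En.n_genes
    if n_top >= G:
        return En
    means = En.values.mean(axis=1)
    var = En.values.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(means > 0, var / means, 0.0)
    # equal-frequency mean bins; z-score dispersion within each bin.
    # bins need several genes each to carry a meaningful z-score
    n_bins = max(1, min(n_bins, G // 10))
    order = np.argsort(means, kind="stable")
    bin_of = np.empty(G, dtype=np.int64)
    bin_of[order] = np.minimum(
        (np.arange(G) * n_bins) // G, n_bins - 1
    )
    z = np.zeros(G)
    for b in range(n_bins):
        idx = bin_of == b
        if not idx.any():
            continue
        d = disp[idx]
        sd = d.std()
        z[idx] = (d - d.mean()) / sd if sd > 0 else 0.0
    # top-n by z, ties by gene index (stable sort on -z)
    ranked = np.argsort(-z, kind="stable")
    keep = np.zeros(G, dtype=bool)
    keep[ranked[:n_top]] = True
    return En.subset(keep, None)


def preprocess(
    E: CountMatrix,
    min_genes_per_cell: int = 1000,
    min_count: int = 5,
    min_cell_frac: float = 0.05,
    normalization: str = "cpm_median",
    n_hvg: int = 1000,
    apply_qc: bool = True,
) -> tuple[CountMatrix, NormalizedMatrix]:
    """QC → normalize → HVG.  Returns (HVG-restricted counts, normalized).

    The returned count matrix is the QC'd raw counts restricted to the
    selected highly variable genes, aligned gene-for-gene with the
    normalized matrix; the count-scale mixture model is fitted on it.
    """
    Eq = qc_filter(E, min_genes_per_cell, min_count, min_cell_frac) if apply_qc else E
    En = normalize_log(Eq, method=normalization)
    Eh = select_hvg(En, n_top=n_hvg)
    gene_pos = pd.Index(Eq.gene_ids).get_indexer(Eh.gene_ids)
    return Eq.subset(gene_pos, None), Eh
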