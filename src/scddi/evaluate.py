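"""Evaluation battery: clustering agreement, expression recovery,
dropout-detection accuracy and paired significance tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score


@dataclass
class EvaluationReport:
    ari: float = float("nan")
    nmi: float = float("nan")
    pearson: float = float("nan")
    spearman: float = float("nan")
    rmse: float = float("nan")
    mae: float = float("nan")
    detection: dict = field(default_factory=dict)
    mean_ci: dict = field(default_factory=dict)
    wilcoxon_p: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "ari": self.ari, "nmi": self.nmi,
            "pearson": self.pearson, "spearman": self.spearman,
            "rmse": self.rmse, "mae": self.mae,
            "detection": self.detection, "mean_ci": self.mean_ci,
            "wilcoxon_p": self.wilcoxon_p,
        }


def cluster_cells(
    En,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """PCA → cosine kNN graph → Leiden community detection.

    Deterministic given ``seed``.  ``n_neighbors`` is reduced (with a
    warning) when there are fewer cells than requested neighbors.
    """
    import anndata as ad
    import scanpy as sc

    X = np.asarray(En.values, dtype=np.float64)
    n_cells = X.shape[1]
    if n_cells < 2:
        raise ValueError("need at least 2 cells to cluster")
    if n_neighbors >= n_cells:
        warnings.warn(
            f"n_neighbors={n_neighbors} >= {n_cells} cells; reducing"
        )
        n_neighbors = max(2, n_cells - 1)
    adata = ad.AnnData(X.T.astype(np.float32))
    n_comps = int(min(n_pcs, n_cells - 1, X.shape[0] - 1))
    sc.pp.pca(adata, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, metric="cosine",
                    random_state=seed)
    sc.tl.leiden(adata, resolution=resolution, random_state=seed,
                 flavor="leidenalg")
    return adata.obs["leiden"].to_numpy().astype(int)


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_rand_score(a, b))


def nmi(labels_a, labels_b) -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    a, b = np.asarray(labels_a), np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    return float(normalized_mutual_info_score(a, b, average_method="arithmetic"))


def recovery_scores(imputed, truth, mask) -> dict:
    """Pearson/Spearman/RMSE/MAE over the masked entries only."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty; nothing to score")
    x = np.asarray(imputed, dtype=np.float64)[mask]
    y = np.asarray(truth, dtype=np.float64)[mask]
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    mae = float(np.mean(np.abs(x - y)))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector under mask; correlations undefined")
        pear = spear = float("nan")
    else:
        pear = float(stats.pearsonr(x, y).statistic)
        spear = float(stats.spearmanr(x, y).statistic)
    return {"pearson": pear, "spearman": spear, "rmse": rmse, "mae": mae}


def detection_metrics(
    D, truth_mask, taus=(0.3, 0.4, 0.5, 0.6, 0.7, 0.8)
) -> dict:
    """Precision/recall/F1 of dropout calls against the planted mask.

    Computed over all matrix entries for each threshold tau (calls =
    probs > tau).  Precision is 0 by convention when there are no calls;
    recall is 0 with a warning when the truth mask is empty.
    """
    truth_mask = np.asarray(truth_mask, dtype=bool)
    probs = np.asarray(D.probs if hasattr(D, "probs") else D, dtype=np.float64)
    if probs.shape != truth_mask.shape:
        raise ValueError("dropout matrix and truth mask shapes differ")
    if not truth_mask.any():
        warnings.warn("empty truth mask; recall undefined, reported as 0")
    out = {}
    for tau in taus:
        calls = probs > tau
        tp = int(np.sum(calls & truth_mask))
        fp = int(np.sum(calls & ~truth_mask))
        fn = int(np.sum(~calls & truth_mask))
        precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if (precision + recall) > 0 else 0.0
        )
        out[float(tau)] = {"precision": precision, "recall": recall, "f1": f1}
    return out


def paired_compare(scores_a, scores_b) -> dict:
    """Paired comparison: means with t-based 95% CIs and a two-sided
    Wilcoxon signed-rank test (exact null for n <= 25)."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1-d of equal length")
    n = len(a)
    if n < 5:
        raise ValueError("need at least 5 paired scores")

    def mean_ci(v):
        m = float(v.mean())
        if np.ptp(v) == 0:
            return {"mean": m, "half_width": 0.0}
        hw = float(stats.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n))
        return {"mean": m, "half_width": hw}

    d = a - b
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p = 1")
        p = 1.0
    else:
        method = "exact" if n <= 25 else "approx"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                                 correction=(method == "approx"))
        p = float(res.pvalue)
    return {"mean_a": mean_ci(a)["mean"], "ci_a": mean_ci(a)["half_width"],
            "mean_b": mean_ci(b)["mean"], "ci_b": mean_ci(b)["half_width"],
            "wilcoxon_p": p}
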