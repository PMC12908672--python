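"""Regression-tree imputation of dropout-flagged entries.

For each target cell, genes not called dropout form the training set:
each gene is a sample whose features are that gene's normalized
expression across the cell's selected neighbors (ordered by descending
similarity) and whose response is the target cell's observed value.  A
CART regression tree (max depth 15, min samples per leaf 10 by default)
is fitted per cell and used to predict the cell's dropout-called genes
from the same neighbor features.  Predictions are clamped at zero;
entries not called dropout are never modified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr
from sklearn.model_selection import GridSearchCV, cross_val_predict
from sklearn.tree import DecisionTreeRegressor


@dataclass
class ImputeParams:
    strategy: str = "tree"         # {"tree", "mean"}
    max_depth: int = 15
    min_samples_leaf: int = 10
    cv_folds: int = 5
    tune: bool = False
    record_cv: bool = False
    min_train_genes: int = 10
    min_neighbors: int = 3
    seed: int = 0


@dataclass
class ImputationResult:
    values: np.ndarray
    imputed_mask: np.ndarray
    per_cell_report: dict = field(default_factory=dict)


def build_training_table(En, D, cell: int, nbrs):
    """Assemble the per-cell regression tables.

    Returns ``(train_X, train_y, predict_X, predict_genes)`` where rows
    are genes and columns are the cell's neighbors in descending
    similarity order.
    """
    X = En.values
    calls = D.calls[:, cell]
    nbr_idx = [i for i, _ in nbrs.neighbors[cell]]
    feats = X[:, nbr_idx]                      # genes x neighbors
    train_rows = ~calls
    predict_rows = calls
    return (
        feats[train_rows],
        X[train_rows, cell],
        feats[predict_rows],
        np.flatnonzero(predict_rows),
    )


def fit_cell_regressor(
    train_X,
    train_y,
    max_depth: int = 15,
    min_samples_leaf: int = 10,
    cv_folds: int = 5,
    tune: bool = False,
    record_cv: bool = False,
    seed: int = 0,
):
    """Fit the per-cell CART regression tree.

    With ``tune=True`` a small grid (depth 5/10/15/20 x leaf 5/10/20) is
    searched by ``cv_folds``-fold cross-validated RMSE, ties resolved
    toward the simpler model.  Returns ``(model, cv_score)`` where
    cv_score is the Spearman correlation of held-out predictions (NaN
    when not requested).
    """
    train_X = np.asarray(train_X, dtype=np.float64)
    train_y = np.asarray(train_y, dtype=np.float64)
    n = train_X.shape[0]
    if n < min_samples_leaf:
        raise ValueError(
            f"{n} training genes is fewer than min_samples_leaf="
            f"{min_samples_leaf}"
        )
    if tune:
        grid = [
            {"max_depth": d, "min_samples_leaf": l}
            for d in (5, 10, 15, 20) for l in (5, 10, 20)
        ]
        # sort so that on ties GridSearchCV's first-best is the simplest
        grid.sort(key=lambda p: (p["max_depth"], -p["min_samples_leaf"]))
        search = GridSearchCV(
            DecisionTreeRegressor(random_state=seed),
            {"max_depth": sorted({p["max_depth"] for p in grid}),
             "min_samples_leaf": sorted({p["min_samples_leaf"] for p in grid},
                                        reverse=True)},
            scoring="neg_root_mean_squared_error",
            cv=min(cv_folds, n),
        )
        search.fit(train_X, train_y)
        model = search.best_estimator_
    else:
        model = DecisionTreeRegressor(
            max_depth=max_depth,
            min_samples_leaf=min_samples_leaf,
            random_state=seed,
        )
        model.fit(train_X, train_y)
    cv_score = float("nan")
    if record_cv or tune:
        folds = min(cv_folds, n)
        if folds >= 2 and np.ptp(train_y) > 0:
            pred = cross_val_predict(
                DecisionTreeRegressor(
                    max_depth=model.max_depth,
                    min_samples_leaf=model.min_samples_leaf,
                    random_state=seed,
                ),
                train_X, train_y, cv=folds,
            )
            rho = spearmanr(pred, train_y).statistic
            cv_score = float(rho) if np.isfinite(rho) else float("nan")
    return model, cv_score


def impute_cell(En, D, cell: int, nbrs, params: ImputeParams):
    """Predict the dropout-called genes of one cell.

    Returns ``(gene_indices, values, report)``; empty when the cell has no
    dropout calls or no usable neighbors.
    """
    report = {"n_imputed": 0, "n_train_genes": 0,
              "fallback_used": False, "cv_score": float("nan")}
    if len(nbrs.neighbors[cell]) < params.min_neighbors:
        report["fallback_used"] = True
        return np.array([], dtype=np.int64), np.array([]), report
    train_X, train_y, predict_X, predict_genes = build_training_table(
        En, D, cell, nbrs
    )
    report["n_train_genes"] = int(len(train_y))
    if predict_genes.size == 0:
        return predict_genes, np.array([]), report
    use_mean = (
        params.strategy == "mean"
        or len(train_y) < max(params.min_train_genes, params.min_samples_leaf)
    )
    if use_mean:
        preds = predict_X.mean(axis=1)
        report["fallback_used"] = params.strategy != "mean"
    elif np.ptp(train_y) == 0:
        preds = np.full(predict_genes.size, train_y[0] if len(train_y) else 0.0)
    else:
        model, cv_score = fit_cell_regressor(
            train_X, train_y,
            max_depth=params.max_depth,
            min_samples_leaf=params.min_samples_leaf,
            cv_folds=params.cv_folds,
            tune=params.tune,
            record_cv=params.record_cv,
            seed=params.seed,
        )
        report["cv_score"] = cv_score
        preds = model.predict(predict_X)
    preds = np.maximum(preds, 0.0)
    report["n_imputed"] = int(predict_genes.size)
    return predict_genes, preds, report


def impute_matrix(En, D, nbrs, params: ImputeParams | None = None) -> ImputationResult:
    """Impute every dropout-called entry, cell by cell.

    Cells are processed independently; entries not called dropout are
    bit-identical to the input.  Deterministic given the seed in
    ``params``.
    """
    if params is None:
        params = ImputeParams()
    X = np.asarray(En.values, dtype=np.float64)
    if D.calls.shape != X.shape:
        raise ValueError("dropout matrix shape does not match expression")
    out = X.copy()
    mask = np.zeros_like(X, dtype=bool)
    reports = {}
    for j in range(X.shape[1]):
        genes, vals, rep = impute_cell(En, D, j, nbrs, params)
        out[genes, j] = vals
        mask[genes, j] = True
        cell_id = En.cell_ids[j] if getattr(En, "cell_ids", None) is not None else j
        reports[cell_id] = rep
    n_failed = sum(
        1 for r in reports.values() if r["fallback_used"] and r["n_imputed"] == 0
    )
    if reports and n_failed == len(reports) and any(
        D.calls[:, j].any() for j in range(X.shape[1])
    ):
        raise RuntimeError("imputation failed for every cell")
    return ImputationResult(values=out, imputed_mask=mask, per_cell_report=reports)
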