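"""End-to-end orchestration: preprocess → dropout model → similarity →
neighbor selection → imputation, plus the simulation benchmarks
(expression recovery under controlled dropout, clustering gain).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evaluate as ev
from .dropout_model import DropoutMatrix, dropout_matrix, write_dropout
from .imputer import ImputationResult, ImputeParams, impute_matrix
from .io_preprocess import CountMatrix, NormalizedMatrix, preprocess, write_matrix
from .similarity import select_neighbors, similarity_matrix, write_similarity
from .simulate import SimTruth, apply_random_dropout, simulate_preset


@dataclass
class RunConfig:
    """All pipeline parameters with their default values."""

    tau: float = 0.5
    sim_cut: float = 75.0
    k: int = 20
    min_neighbors: int = 3
    strategy: str = "tree"            # {"tree", "mean"}
    similarity: str = "wcs"           # {"wcs", "cosine"}
    dropout_model: str = "pnb"        # {"pnb", "logistic"}
    max_depth: int = 15
    min_samples_leaf: int = 10
    cv_folds: int = 5
    tune: bool = False
    n_hvg: int = 1000
    min_genes_per_cell: int = 1000
    min_count: int = 5
    min_cell_frac: float = 0.05
    apply_qc: bool = True
    n_pcs: int = 50
    n_neighbors: int = 15
    resolution: float = 1.0
    preset: str = "dataset1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError(f"tau={self.tau} must lie in [0, 1]")
        if not 0.0 <= self.sim_cut <= 100.0:
            raise ValueError(f"sim_cut={self.sim_cut} must lie in [0, 100]")
        if self.k < 1 or self.min_neighbors < 1:
            raise ValueError("k and min_neighbors must be >= 1")
        if self.strategy not in ("tree", "mean"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.similarity not in ("wcs", "cosine"):
            raise ValueError(f"unknown similarity mode {self.similarity!r}")
        if self.dropout_model not in ("pnb", "logistic"):
            raise ValueError(f"unknown dropout model {self.dropout_model!r}")
        if self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ValueError("tree hyperparameters must be >= 1")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")
        if not isinstance(self.seed, (int, np.integer)) or self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PipelineResult:
    counts_hvg: CountMatrix
    normalized: NormalizedMatrix
    dropout: DropoutMatrix
    similarity: object
    neighbors: object
    imputation: ImputationResult
    config: RunConfig

    @property
    def imputed(self) -> NormalizedMatrix:
        """Imputed expression as a NormalizedMatrix (log2 scale)."""
        return NormalizedMatrix(
            self.imputation.values,
            self.normalized.gene_ids,
            self.normalized.cell_ids,
            self.normalized.normalization_tag + "+imputed",
        )


def run_imputation(E: CountMatrix, config: RunConfig | None = None) -> PipelineResult:
    """Run the full in-memory pipeline on a raw count matrix."""
    cfg = config or RunConfig()
    counts_hvg, En = preprocess(
        E,
        min_genes_per_cell=cfg.min_genes_per_cell,
        min_count=cfg.min_count,
        min_cell_frac=cfg.min_cell_frac,
        n_hvg=cfg.n_hvg,
        apply_qc=cfg.apply_qc,
    )
    D = dropout_matrix(counts_hvg, tau=cfg.tau, model=cfg.dropout_model)
    S = similarity_matrix(En, D, mode=cfg.similarity)
    nbrs = select_neighbors(S, sim_cut=cfg.sim_cut, k=cfg.k,
                            min_neighbors=cfg.min_neighbors)
    params = ImputeParams(
        strategy=cfg.strategy,
        max_depth=cfg.max_depth,
        min_samples_leaf=cfg.min_samples_leaf,
        cv_folds=cfg.cv_folds,
        tune=cfg.tune,
        min_neighbors=cfg.min_neighbors,
        seed=cfg.seed,
    )
    imp = impute_matrix(En, D, nbrs, params)
    return PipelineResult(counts_hvg, En, D, S, nbrs, imp, cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, input_path=None, input_format: str = "csv",
                 outdir="scddi_out") -> Path:
    """Run the pipeline on a file (or a simulated preset) and write all
    artifacts plus a manifest with content hashes.

    Re-running with the same configuration reproduces identical outputs.
    """
    from .io_preprocess import read_counts

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if input_path is None:
        truth = simulate_preset(config.preset, seed=config.seed)
        E = truth.observed_matrix()
    else:
        E = read_counts(input_path, format=input_format)
    res = run_imputation(E, config)

    write_matrix(res.imputed, outdir / "imputed.csv", "csv")
    pd.DataFrame(
        res.imputation.imputed_mask.astype(int),
        index=res.normalized.gene_ids, columns=res.normalized.cell_ids,
    ).to_csv(outdir / "imputed_mask.csv")
    pd.DataFrame.from_dict(res.imputation.per_cell_report, orient="index").to_csv(
        outdir / "per_cell_report.tsv", sep="\t")
    write_matrix(res.normalized, outdir / "normalized.csv", "csv")
    write_dropout(res.dropout, outdir)
    write_similarity(res.similarity, res.neighbors, outdir)

    artifacts = sorted(
        p.name for p in outdir.iterdir()
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": asdict(config),
        "artifacts": {name: _sha256(outdir / name) for name in artifacts},
        "n_genes": int(res.normalized.n_genes),
        "n_cells": int(res.normalized.n_cells),
        "n_imputed": int(res.imputation.imputed_mask.sum()),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir


# ---------------------------------------------------------------------------
# simulation benchmarks
# ---------------------------------------------------------------------------

def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from one master seed."""
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def recovery_experiment(
    preset: str = "dataset1",
    rate: float = 0.4,
    seed: int = 0,
    config: RunConfig | None = None,
    with_detection: bool = False,
    sim_overrides: dict | None = None,
) -> dict:
    """Controlled-dropout recovery: simulate, corrupt, impute, score.

    Exactly ``rate`` of the nonzero true counts are zeroed; the pipeline
    imputes the corrupted matrix and Pearson/Spearman/RMSE/MAE are
    computed on the masked entries (log2-normalized scale) of the HVG
    submatrix.  QC is skipped: simulated matrices contain no low-quality
    cells, and heavy corruption would otherwise empty the cell filter.
    """
    cfg = config or RunConfig()
    sim_seed, drop_seed, imp_seed = _derive_seeds(seed, 3)
    truth = simulate_preset(preset, seed=sim_seed, **(sim_overrides or {}))
    corrupted = apply_random_dropout(truth, rate, seed=drop_seed)
    cfg = RunConfig(**{**asdict(cfg), "apply_qc": False, "seed": imp_seed})
    res = run_imputation(corrupted.observed_matrix(), cfg)

    # align the ground truth with the pipeline's HVG gene subset
    gene_pos = pd.Index([f"gene{i}" for i in range(truth.n_genes)]).get_indexer(
        res.normalized.gene_ids
    )
    from .io_preprocess import normalize_log

    truth_norm = normalize_log(truth.true_matrix()).subset(gene_pos, None)
    mask_hvg = corrupted.dropout_mask[gene_pos, :]
    scores = ev.recovery_scores(res.imputation.values, truth_norm.values, mask_hvg)
    out = {"preset": preset, "rate": rate, "seed": seed,
           "n_masked": int(mask_hvg.sum()), **scores}
    if with_detection:
        out["detection"] = ev.detection_metrics(res.dropout, mask_hvg)
    return out


def clustering_experiment(
    preset: str = "dataset1",
    seed: int = 0,
    config: RunConfig | None = None,
    variants: tuple = (),
    sim_overrides: dict | None = None,
) -> dict:
    """Clustering gain: ARI/NMI against true group labels, raw vs imputed.

    ``variants`` may list additional (name, RunConfig) pairs — e.g. the
    ablation configurations — which reuse the same simulation and are
    clustered identically.
    """
    cfg = config or RunConfig()
    sim_seed, imp_seed, clu_seed = _derive_seeds(seed, 3)
    truth = simulate_preset(preset, seed=sim_seed, **(sim_overrides or {}))
    E = truth.observed_matrix()
    cfg = RunConfig(**{**asdict(cfg), "seed": imp_seed})
    res = run_imputation(E, cfg)

    cell_pos = pd.Index(
        [f"cell{j}" for j in range(truth.n_cells)]
    ).get_indexer(res.normalized.cell_ids)
    labels_true = truth.group_labels[cell_pos]

    labels_raw = ev.cluster_cells(res.normalized, n_pcs=cfg.n_pcs,
                                  n_neighbors=cfg.n_neighbors,
                                  resolution=cfg.resolution, seed=clu_seed)
    labels_imp = ev.cluster_cells(res.imputed, n_pcs=cfg.n_pcs,
                                  n_neighbors=cfg.n_neighbors,
                                  resolution=cfg.resolution, seed=clu_seed)
    out = {
        "preset": preset, "seed": seed,
        "ari_raw": ev.ari(labels_true, labels_raw),
        "ari_imputed": ev.ari(labels_true, labels_imp),
        "nmi_raw": ev.nmi(labels_true, labels_raw),
        "nmi_imputed": ev.nmi(labels_true, labels_imp),
    }
    for name, vcfg in variants:
        vcfg = RunConfig(**{**asdict(vcfg), "seed": imp_seed})
        vres = run_imputation(E, vcfg)
        labels_v = ev.cluster_cells(vres.imputed, n_pcs=cfg.n_pcs,
                                    n_neighbors=cfg.n_neighbors,
                                    resolution=cfg.resolution, seed=clu_seed)
        out[f"ari_{name}"] = ev.ari(labels_true, labels_v)
        out[f"nmi_{name}"] = ev.nmi(labels_true, labels_v)
    return out


def ablation_experiment(
    preset: str = "dataset1",
    seed: int = 0,
    config: RunConfig | None = None,
    sim_overrides: dict | None = None,
) -> dict:
    """Single-substitution ablation on one simulated dataset.

    Runs the full configuration (PNB dropout model, WCS similarity, tree
    regression) and the three single-substitution variants (mean
    imputation, plain cosine similarity, logistic dropout surrogate),
    sharing every stage that the substitution does not touch, and scores
    each clustering against the true group labels.
    """
    cfg = config or RunConfig()
    sim_seed, imp_seed, clu_seed = _derive_seeds(seed, 3)
    truth = simulate_preset(preset, seed=sim_seed, **(sim_overrides or {}))
    E = truth.observed_matrix()
    counts_hvg, En = preprocess(
        E, min_genes_per_cell=cfg.min_genes_per_cell, min_count=cfg.min_count,
        min_cell_frac=cfg.min_cell_frac, n_hvg=cfg.n_hvg,
        apply_qc=cfg.apply_qc,
    )
    cell_pos = pd.Index(
        [f"cell{j}" for j in range(truth.n_cells)]
    ).get_indexer(En.cell_ids)
    labels_true = truth.group_labels[cell_pos]

    D_pnb = dropout_matrix(counts_hvg, tau=cfg.tau, model="pnb")
    D_log = dropout_matrix(counts_hvg, tau=cfg.tau, model="logistic")
    S_wcs = similarity_matrix(En, D_pnb, mode="wcs")
    S_cos = similarity_matrix(En, D_pnb, mode="cosine")
    S_logw = similarity_matrix(En, D_log, mode="wcs")
    nb = lambda S: select_neighbors(S, sim_cut=cfg.sim_cut, k=cfg.k,
                                    min_neighbors=cfg.min_neighbors)
    tree = ImputeParams(strategy="tree", max_depth=cfg.max_depth,
                        min_samples_leaf=cfg.min_samples_leaf,
                        min_neighbors=cfg.min_neighbors, seed=imp_seed)
    mean = ImputeParams(strategy="mean", min_neighbors=cfg.min_neighbors,
                        seed=imp_seed)
    variants = {
        "full": impute_matrix(En, D_pnb, nb(S_wcs), tree),
        "mean": impute_matrix(En, D_pnb, nb(S_wcs), mean),
        "cosine": impute_matrix(En, D_pnb, nb(S_cos), tree),
        "logistic": impute_matrix(En, D_log, nb(S_logw), tree),
    }

    def _cluster(values):
        M = NormalizedMatrix(values, En.gene_ids, En.cell_ids)
        return ev.cluster_cells(M, n_pcs=cfg.n_pcs,
                                n_neighbors=cfg.n_neighbors,
                                resolution=cfg.resolution, seed=clu_seed)

    out = {"preset": preset, "seed": seed}
    labels_raw = _cluster(En.values)
    out["ari_raw"] = ev.ari(labels_true, labels_raw)
    out["nmi_raw"] = ev.nmi(labels_true, labels_raw)
    for name, imp in variants.items():
        lab = _cluster(imp.values)
        out[f"ari_{name}"] = ev.ari(labels_true, lab)
        out[f"nmi_{name}"] = ev.nmi(labels_true, lab)
    return out


def run_benchmark(
    presets=("dataset1",),
    rates=(),
    seeds=(0, 1, 2),
    config: RunConfig | None = None,
    sim_overrides: dict | None = None,
) -> dict:
    """Loop presets × rates × seeds; aggregate with means, CIs and (for
    clustering runs with >= 5 seeds) a paired signed-rank test of
    imputed vs raw ARI."""
    if not presets:
        raise ValueError("preset list must not be empty")
    cfg = config or RunConfig()
    reports = []
    for preset in presets:
        if rates:
            for rate in rates:
                for seed in seeds:
                    reports.append(recovery_experiment(
                        preset, rate, seed, cfg, sim_overrides=sim_overrides))
        else:
            for seed in seeds:
                reports.append(clustering_experiment(
                    preset, seed, cfg, sim_overrides=sim_overrides))
    agg: dict = {"n_runs": len(reports)}
    keys = [k for k in reports[0]
            if isinstance(reports[0][k], float) and k not in ("rate",)]
    for key in keys:
        v = np.array([r[key] for r in reports], dtype=np.float64)
        m = float(np.nanmean(v))
        if len(v) >= 2 and np.ptp(v[~np.isnan(v)]) > 0:
            from scipy import stats as st
            hw = float(st.t.ppf(0.975, len(v) - 1)
                       * np.nanstd(v, ddof=1) / np.sqrt(len(v)))
        else:
            hw = 0.0
        agg[key] = {"mean": m, "half_width": hw}
    if not rates and len(reports) >= 5:
        agg["paired"] = ev.paired_compare(
            [r["ari_imputed"] for r in reports],
            [r["ari_raw"] for r in reports],
        )
    return {"reports": reports, "aggregate": agg}
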