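"""End-to-end workflow: ingest -> label -> SWT -> CNN -> gene scoring -> Cox risk model.

`run_pipeline` performs one full training/validation pass: it filters genes,
derives endpoint labels, splits the cohort once, selects the wavelet and the
network on the training part only, back-maps representative features to gene
scores, builds the Cox risk signature with a ROC cutoff, and finally — and
only then — touches the validation samples to report AUCs, stratification
and the log-rank test.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import ingest, scoring, survival, wavelet as wv
from .cnn import ConvNetClassifier, repeat_train_select_best
from .metrics import auc

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything `run_pipeline` needs besides the data itself."""

    endpoint: str = "survival3y"           # or "stage"
    horizon_days: float = ingest.THREE_YEARS_DAYS
    train_fraction: float = 0.7
    wavelet: str = "db3"                   # a wavelet name, or "auto" to search
    wavelet_candidates: tuple = wv.WAVELET_FUNCTIONS
    levels: int = 3
    n_filters: int = 64
    kernel_length: int = 8
    pool_window: int = 8
    dense_units: int = 32
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 16
    n_runs: int = 100                      # best-of-N model selection on the training set
    y_source: str = "expression"           # or "swt_level1" for Eq.-style coefficient scores
    top_n: int | None = None               # fixed signature-pool size; None = tune on the grid
    top_n_grid: tuple = tuple(range(100, 1001, 100))
    cox_alpha: float = 0.05
    seed: int = 0
    log_transform: bool = False            # log2(x+1) before everything (off: raw FPKM-like)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["wavelet_candidates"] = list(d["wavelet_candidates"])
        d["top_n_grid"] = list(d["top_n_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "wavelet_candidates" in d:
            d["wavelet_candidates"] = tuple(d["wavelet_candidates"])
        if "top_n_grid" in d:
            d["top_n_grid"] = tuple(d["top_n_grid"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _finite_or_none(x):
    return float(x) if x is not None and x is not False and np.isfinite(x) else None


def _derive_cohort(clinical: pd.DataFrame, cfg: PipelineConfig) -> ingest.LabeledCohort:
    if cfg.endpoint == "stage":
        return ingest.derive_stage_labels(clinical)
    if cfg.endpoint == "survival3y":
        return ingest.derive_survival_labels(clinical, horizon_days=cfg.horizon_days)
    raise ValueError(f"unknown endpoint {cfg.endpoint!r}")


def run_pipeline(expr: pd.DataFrame, clinical: pd.DataFrame, cfg: PipelineConfig,
                 outdir: str | Path | None = None) -> dict:
    """Run the full workflow once; returns an artifact dictionary.

    Keys: cohort, train_ids/val_ids, wavelet, cnn (fitted), score_table,
    top_n, risk_model, metrics (dict), km (KMResult). If ``outdir`` is set,
    tables, the model archive, metrics JSON and a manifest are written there.
    """
    stage = "ingest"
    try:
        expr = ingest.filter_low_expression(expr)
        if cfg.log_transform:
            expr = np.log2(expr + 1.0)

        stage = "labelling"
        cohort = _derive_cohort(clinical[clinical["sample_id"].isin(expr.columns)], cfg)
        expr = expr[list(cohort.sample_ids)]

        stage = "splitting"
        plan = ingest.make_splits(cohort, train_fraction=cfg.train_fraction, repeats=1, seed=cfg.seed)
        train_ids, val_ids = plan.splits[0]
        tr = np.isin(cohort.sample_ids, train_ids)
        va = ~tr
        expr_tr = expr.loc[:, tr]
        y_tr = cohort.labels[tr]

        stage = "wavelet selection"
        if cfg.wavelet == "auto":
            spec = wv.select_wavelet(
                expr_tr.to_numpy().T, y_tr, cfg.wavelet_candidates, levels=cfg.levels,
                random_state=cfg.seed, n_filters=cfg.n_filters, kernel_length=cfg.kernel_length,
                pool_window=cfg.pool_window, dense_units=cfg.dense_units,
                learning_rate=cfg.learning_rate, epochs=cfg.epochs, batch_size=cfg.batch_size,
            )
        else:
            spec = wv.WaveletSpec(cfg.wavelet, cfg.levels)

        stage = "wavelet decomposition"
        tensor_tr, _ = wv.decompose_cohort(expr_tr.to_numpy(), spec)

        stage = "cnn training"
        cnn = repeat_train_select_best(
            tensor_tr, y_tr, runs=cfg.n_runs, random_state=cfg.seed,
            n_filters=cfg.n_filters, kernel_length=cfg.kernel_length,
            pool_window=cfg.pool_window, dense_units=cfg.dense_units,
            learning_rate=cfg.learning_rate, epochs=cfg.epochs, batch_size=cfg.batch_size,
        )

        stage = "gene scoring"
        X_feat = cnn.representative_features(tensor_tr)          # f x n_train
        if cfg.y_source == "expression":
            Y = expr_tr.to_numpy()
        elif cfg.y_source == "swt_level1":
            Y = tensor_tr[:, :, 0].T
        else:
            raise ValueError(f"unknown y_source {cfg.y_source!r}")
        B = scoring.score_matrix(Y, X_feat)
        score_table = scoring.gene_scores(B, expr_tr.index.to_numpy())

        stage = "top-n tuning"
        os_tr = cohort.os_days[tr]
        ev_tr = cohort.event[tr]
        if cfg.top_n is not None:
            top_n = int(cfg.top_n)
        else:
            grid = [n for n in cfg.top_n_grid if n <= len(score_table)] or [min(100, len(score_table))]
            top_n = survival.tune_top_n(expr_tr, score_table, os_tr, ev_tr, y_tr,
                                        grid=grid, random_state=cfg.seed, alpha=cfg.cox_alpha)

        stage = "cox regression"
        pool = scoring.top_n_genes(score_table, min(top_n, len(score_table)))
        uni = survival.univariate_cox(expr_tr.loc[pool], os_tr, ev_tr, alpha=cfg.cox_alpha)
        selected = uni.loc[uni["selected"], "gene_id"].tolist()
        if not selected:
            raise ValueError("no univariately significant gene in the top-n pool")
        model = survival.multivariate_cox(expr_tr.loc[selected], os_tr, ev_tr,
                                          alpha=cfg.cox_alpha, random_state=cfg.seed)

        stage = "cutoff"
        scores_tr = survival.risk_score(model, expr_tr)
        model.cutoff = survival.choose_cutoff_roc(scores_tr, y_tr)

        # --- validation samples are first touched below this line ---
        stage = "validation"
        expr_va = expr.loc[:, va]
        y_va = cohort.labels[va]
        tensor_va, _ = wv.decompose_cohort(expr_va.to_numpy(), spec)
        cnn_auc = auc(y_va, cnn.decision_scores(tensor_va))
        scores_va = survival.risk_score(model, expr_va)
        risk_auc = auc(y_va, scores_va)
        groups_va = survival.stratify(scores_va, model.cutoff)

        km = None
        if len(np.unique(groups_va)) == 2:
            km = survival.km_logrank(groups_va, cohort.os_days[va], cohort.event[va])

        metrics = {
            "endpoint": cfg.endpoint,
            "seed": cfg.seed,
            "wavelet": spec.function,
            "levels": spec.levels,
            "n_genes": int(expr.shape[0]),
            "n_samples": int(len(cohort)),
            "n_train": int(tr.sum()),
            "n_validation": int(va.sum()),
            "top_n": int(top_n),
            "n_univariate_selected": int(len(selected)),
            "signature_size": int(len(model.gene_ids)),
            "fit_mode": model.fit_mode,
            "cutoff": float(model.cutoff),
            "cnn_validation_auc": float(cnn_auc),
            "risk_score_validation_auc": float(risk_auc),
            "logrank_statistic": None if km is None else km.statistic,
            "logrank_p_value": None if km is None else km.p_value,
            # None when the KM curve never crosses 0.5 (median not reached)
            "median_survival_high": _finite_or_none(km and km.medians.get(1)),
            "median_survival_low": _finite_or_none(km and km.medians.get(0)),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    artifacts = {
        "cohort": cohort,
        "train_ids": train_ids,
        "val_ids": val_ids,
        "wavelet": spec,
        "cnn": cnn,
        "score_table": score_table,
        "top_n": top_n,
        "univariate": uni,
        "risk_model": model,
        "validation_scores": scores_va,
        "validation_groups": groups_va,
        "km": km,
        "metrics": metrics,
    }
    if outdir is not None:
        _write_artifacts(Path(outdir), cfg, artifacts)
    return artifacts


def _write_artifacts(outdir: Path, cfg: PipelineConfig, art: dict) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    art["score_table"].to_csv(outdir / "gene_scores.tsv", sep="\t", index=False)
    art["univariate"].to_csv(outdir / "univariate_cox.tsv", sep="\t", index=False)
    art["risk_model"].to_json(outdir / "risk_model.json")
    art["cnn"].save(outdir / "cnn_model.npz")
    risk_tbl = pd.DataFrame(
        {
            "sample_id": art["val_ids"],
            "risk_score": art["validation_scores"],
            "group": np.where(art["validation_groups"] == 1, "high", "low"),
        }
    )
    risk_tbl.to_csv(outdir / "risk_table.tsv", sep="\t", index=False)
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(art["metrics"], fh, indent=2)
    manifest = {"config": cfg.to_dict(), "config_hash": cfg.config_hash(), "seed": cfg.seed}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline artifacts written to %s", outdir)
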