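"""End-to-end orchestration of the two-phase pipeline for one drug.

Phase 1: preprocess (filter + gene intersection), normalize source and
target (mode from config), tune hyperparameters by cross-validated grid
search, train the mean ensemble, predict the target cohort, and evaluate.

Phase 2: compute masking-based contribution targets on the training cohort,
distill them into an explainer ensemble, score the target samples, aggregate
per-drug gene scores, and cut the top-gene panel at the knee.

A :class:`RunManifest` records the config snapshot, seeds, input hashes,
library versions, stage timings and output paths so a run is reproducible
from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .core_io import (ExpressionMatrix, PipelineConfig, ResponseTable,
                      filter_target_genes, intersect_genes)
from .evaluation import EvalReport, domain_distance_per_member, evaluate_predictions
from .explainer import (ContributionSet, DrugGeneScores, aggregate_scores,
                        granger_contributions, score_samples, train_explainer)
from .gene_selection import KneeResult, select_panel
from .normalization import (apply_normalizer, fit_tissue_informed, fit_zscore,
                            normalize_labels)
from .predictor import TrainedPredictor, train_ensemble, tune_hyperparameters

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    """Provenance record for one pipeline execution."""

    config: dict
    input_hashes: dict
    base_seed: int
    versions: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    output_paths: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


@dataclass
class PipelineResult:
    """Everything a single-drug run produces."""

    predictions: dict[str, float]
    model: TrainedPredictor
    explainer_scores: DrugGeneScores
    knee: KneeResult
    report: EvalReport
    manifest: RunManifest
    source_normalized: ExpressionMatrix
    target_normalized: ExpressionMatrix
    contributions: ContributionSet


def _hash_matrix(m: ExpressionMatrix) -> str:
    h = hashlib.sha256()
    h.update(",".join(m.sample_ids).encode())
    h.update(",".join(m.gene_ids).encode())
    h.update(np.ascontiguousarray(m.values).tobytes())
    return h.hexdigest()[:16]


def normalize_cohorts(config: PipelineConfig, source: ExpressionMatrix,
                      target: ExpressionMatrix, pool: ExpressionMatrix | None
                      ) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Apply the configured normalization mode to both cohorts.

    The source cohort is always z-scored against itself; the mode decides
    the reference for the target cohort.
    """
    src_stats = fit_zscore(source, mode="train_norm")
    src_norm = apply_normalizer(source, src_stats)
    mode = config.normalization_mode
    if mode == "tissue_informed":
        if pool is None:
            raise ValueError("tissue_informed mode needs an unlabeled pool")
        if target.tissue is None:
            raise ValueError("tissue_informed mode needs target tissue labels")
        t_d = sorted(set(target.tissue))
        tgt_stats = fit_tissue_informed(pool, t_d,
                                        exclude_samples=target.sample_ids)
    elif mode == "train_norm":
        tgt_stats = src_stats
    else:  # test_norm
        tgt_stats = fit_zscore(target, mode="test_norm")
    return src_norm, apply_normalizer(target, tgt_stats)


def restrict_to_panel(model: TrainedPredictor,
                      matrix: ExpressionMatrix | np.ndarray,
                      panel: list[str]) -> np.ndarray:
    """Predict with all non-panel genes zeroed in normalized space.

    Zeroing a normalized gene pins it at its reference mean, so this
    measures the predictive power carried by the panel alone.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    unknown = sorted(set(panel) - set(model.gene_ids))
    if unknown:
        raise KeyError(f"panel genes not in the model: {unknown[:10]}")
    X = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix)
    if isinstance(matrix, ExpressionMatrix) and \
            list(matrix.gene_ids) != list(model.gene_ids):
        raise ValueError("gene order does not match the trained model")
    keep = np.isin(np.asarray(model.gene_ids), np.asarray(list(panel)))
    return model.predict(np.where(keep[None, :], X, 0.0))


def run_pipeline(config: PipelineConfig,
                 source: ExpressionMatrix, source_response: ResponseTable,
                 target: ExpressionMatrix, target_labels: ResponseTable | None,
                 pool: ExpressionMatrix | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Execute every stage in order; any stage error aborts with the stage
    name recorded in the manifest (written to ``outdir`` when given)."""
    manifest = RunManifest(
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in vars(config).items()},
        input_hashes={"source": _hash_matrix(source), "target": _hash_matrix(target),
                      **({"pool": _hash_matrix(pool)} if pool is not None else {})},
        base_seed=config.base_seed,
        versions={"drtransfer": __version__, "numpy": np.__version__})
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    state: dict = {}
    stage = "start"

    def run_stage(name, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        logger.info("stage %s: start", name)
        fn()
        manifest.stage_seconds[name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s: done in %.2fs", name, manifest.stage_seconds[name])

    def _preprocess():
        tgt = state["target_raw"] = target
        if not tgt.has_transform("log2"):
            tgt = filter_target_genes(tgt)
        src, tgt = intersect_genes(source, tgt)
        pl = pool.subset_genes(tgt.gene_ids) if pool is not None else None
        state.update(source=src, target=tgt, pool=pl)

    def _normalize():
        src_norm, tgt_norm = normalize_cohorts(
            config, state["source"], state["target"], state["pool"])
        y_norm, label_norm = normalize_labels(
            source_response.aligned_to(state["source"]).values, config.drug)
        state.update(src_norm=src_norm, tgt_norm=tgt_norm,
                     y_norm=y_norm, label_norm=label_norm)

    def _tune():
        state["hyperparams"] = tune_hyperparameters(
            state["src_norm"].values, state["y_norm"], config)

    def _train():
        state["model"] = train_ensemble(
            state["src_norm"].values, state["y_norm"], state["hyperparams"],
            K=config.ensemble_size, base_seed=config.base_seed,
            hidden=config.hidden, dropout=config.dropout,
            gene_ids=list(state["src_norm"].gene_ids),
            label_normalizer=state["label_norm"])

    def _predict():
        state["preds"] = state["model"].predict(state["tgt_norm"])

    def _evaluate():
        dist = domain_distance_per_member(state["model"], state["src_norm"],
                                          state["tgt_norm"])
        if target_labels is not None:
            labels = target_labels.aligned_to(state["tgt_norm"]).labels
            state["report"] = evaluate_predictions(
                state["preds"], labels, drug=config.drug,
                percentiles=config.percentiles, domain_dist=dist)
        else:
            state["report"] = EvalReport(drug=config.drug, u_statistic=float("nan"),
                                         p_value=float("nan"), auroc=float("nan"),
                                         domain_distance=dist)

    def _contributions():
        X, y = state["src_norm"].values, state["y_norm"]
        ids = list(state["src_norm"].sample_ids)
        if config.explainer_subsample and config.explainer_subsample < len(y):
            rng = np.random.default_rng(config.base_seed)
            pick = rng.choice(len(y), size=config.explainer_subsample, replace=False)
            X, y, ids = X[pick], y[pick], [ids[i] for i in pick]
        state["targets"] = granger_contributions(state["model"], X, y,
                                                 sample_ids=ids)
        state["expl_X"], state["expl_y"] = X, y

    def _explain():
        state["explainers"] = train_explainer(
            state["model"], state["expl_X"], state["expl_y"],
            n_explainers=config.n_explainers, hidden=config.explainer_hidden,
            layers=config.explainer_layers, epochs=config.explainer_epochs,
            batch_size=config.explainer_batch_size,
            learning_rate=config.explainer_learning_rate,
            base_seed=config.base_seed + 5000, targets=state["targets"])

    def _score():
        pred_scores = score_samples(state["explainers"], state["tgt_norm"])
        labeled = (target_labels.sample_ids if target_labels is not None
                   else pred_scores.sample_ids)
        labeled = [s for s in labeled if s in set(pred_scores.sample_ids)]
        state["pred_scores"] = pred_scores
        state["gene_scores"] = aggregate_scores(pred_scores, labeled,
                                                drug=config.drug)

    def _knee():
        state["knee"] = select_panel(state["gene_scores"])

    def _persist():
        if outdir is None:
            return
        state["model"].save(outdir / "model")
        state["gene_scores"].to_table(outdir / "gene_scores.tsv")
        state["knee"].to_table(outdir / "panel.tsv")
        state["report"].to_json(outdir / "eval_report.json")
        import pandas as pd
        pd.DataFrame({"sample_id": state["tgt_norm"].sample_ids,
                      "prediction": state["preds"]}).to_csv(
            outdir / "predictions.tsv", sep="\t", index=False)
        state["pred_scores"].to_frame().to_csv(outdir / "sample_scores.tsv", sep="\t")
        manifest.output_paths = {k: str(outdir / v) for k, v in {
            "model": "model", "gene_scores": "gene_scores.tsv",
            "panel": "panel.tsv", "report": "eval_report.json",
            "predictions": "predictions.tsv",
            "sample_scores": "sample_scores.tsv"}.items()}

    stages = [("preprocess", _preprocess), ("normalize", _normalize),
              ("tune", _tune), ("train", _train), ("predict", _predict),
              ("evaluate", _evaluate), ("contributions", _contributions),
              ("explain", _explain), ("score", _score), ("knee", _knee),
              ("persist", _persist)]
    try:
        for name, fn in stages:
            run_stage(name, fn)
    except Exception as exc:
        manifest.failed_stage = stage
        if outdir is not None:
            manifest.to_json(outdir / "manifest.json")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    if outdir is not None:
        manifest.to_json(outdir / "manifest.json")

    return PipelineResult(
        predictions=dict(zip(state["tgt_norm"].sample_ids,
                             map(float, state["preds"]))),
        model=state["model"], explainer_scores=state["gene_scores"],
        knee=state["knee"], report=state["report"], manifest=manifest,
        source_normalized=state["src_norm"], target_normalized=state["tgt_norm"],
        contributions=state["pred_scores"])
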