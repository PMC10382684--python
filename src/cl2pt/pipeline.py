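"""End-to-end orchestration: preprocess -> select -> train -> predict -> evaluate.

The in-memory entry points (:func:`run_core`, :func:`ablation_compare`) are
what tests and library users call; :func:`run_end_to_end` wraps them with
file I/O, a manifest, and an output directory layout.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from . import __version__
from .cutoff_adjust import CutoffAdjustment, classify_with_cutoff
from .datasets_io import (
    DataError,
    DomainDataset,
    harmonize_domains,
    intersect_genes,
    load_domain_dataset,
    normalize_housekeeping,
)
from .evaluation import EvaluationReport, confusion_metrics, repeat_summary, roc_auc
from .featsel import select_features
from .predictors import (
    TrainedPredictor,
    TrainingConfig,
    predict_proba,
    train_knnda,
    train_logitda,
)
from .synthetic import SyntheticConfig, generate_domain_pair

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    source_expr: str
    source_resp: str
    target_expr: str
    target_resp: str
    out_dir: str
    alpha: float = 0.7
    method: Literal["logitda", "knnda"] = "logitda"
    seed: int = 0
    repeats: int = 10
    outer_repeats: int = 1
    max_genes: int = 1000
    use_da: bool = True
    harmonize: Literal["location_scale", "none"] = "location_scale"
    hk_gene: str | None = None
    hk_on_target: bool = True
    max_conc: float | None = None
    adjust_cutoff: bool = True
    cutoff: float | None = None  # overrides the adjustment when set
    training: TrainingConfig | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DataError(f"alpha must lie in (0,1), got {self.alpha}")


def preprocess_pair(
    source: DomainDataset,
    target: DomainDataset,
    hk_gene: str | None = None,
    hk_on_target: bool = True,
    harmonize: Literal["location_scale", "none"] = "location_scale",
) -> tuple[DomainDataset, DomainDataset]:
    """Housekeeping normalization (optional), gene intersection, harmonization."""
    se, te = source.expr, target.expr
    if hk_gene is not None:
        se = normalize_housekeeping(se, hk_gene)
        if hk_on_target:
            te = normalize_housekeeping(te, hk_gene)
    se, te = intersect_genes(se, te)
    se, te = harmonize_domains(se, te, method=harmonize)
    logger.info("preprocessed: %d shared genes", se.n_genes)
    return (
        DomainDataset(se, source.labels, "source", source.drug_name),
        DomainDataset(te, target.labels, "target", target.drug_name),
    )


def run_core(
    source: DomainDataset,
    target: DomainDataset,
    alpha: float = 0.7,
    method: Literal["logitda", "knnda"] = "logitda",
    max_genes: int = 1000,
    use_da: bool = True,
    adjust_cutoff: bool = True,
    cutoff: float | None = None,
    training: TrainingConfig | None = None,
    outer_repeats: int = 1,
) -> dict:
    """Select features, train, score the target cohort and evaluate.

    ``outer_repeats`` re-runs training with distinct CV seeds to yield the
    mean and s.e. of the target AUC.  Returns a dict with the ranking,
    fitted model, target scores, cutoff info and evaluation report.
    """
    training = training or TrainingConfig()
    ranking = select_features(
        source, target, alpha=alpha, max_genes=max_genes, use_da=use_da
    )
    if len(ranking) < min(training.p_grid):
        logger.warning(
            "ranking has %d genes, below the smallest grid p (%d); "
            "using p = %d", len(ranking), min(training.p_grid), len(ranking),
        )
        training = TrainingConfig(**{**asdict(training), "p_grid": (len(ranking),)})
    trainer = train_logitda if method == "logitda" else train_knnda
    models: list[TrainedPredictor] = []
    aucs: list[float] = []
    for rep in range(outer_repeats):
        cfg = TrainingConfig(**{**asdict(training), "seed": training.seed + rep})
        model = trainer(source, ranking, cfg)
        scores = predict_proba(model, target.expr)
        models.append(model)
        aucs.append(roc_auc(scores, target.labels.y))
    model = models[0]
    scores = predict_proba(model, target.expr)

    adjustment = None
    if cutoff is not None:
        used_cutoff = cutoff
    elif adjust_cutoff and method == "logitda":
        adjustment = CutoffAdjustment.from_labels(source.labels, target.labels)
        used_cutoff = adjustment.cutoff
    else:
        if adjust_cutoff and method == "knnda":
            logger.warning(
                "cutoff adjustment applies to continuous probabilities only; "
                "using 0.5 for knnda"
            )
        used_cutoff = 0.5

    pred = classify_with_cutoff(scores, used_cutoff)
    conf = confusion_metrics(pred, target.labels.y)
    if outer_repeats >= 2:
        auc_mean, auc_se = repeat_summary(np.array(aucs))
    else:
        auc_mean, auc_se = float(aucs[0]), 0.0
    report = EvaluationReport(
        auc_mean=auc_mean,
        auc_se=auc_se,
        accuracy=conf.accuracy,
        fpr=conf.fpr,
        fnr=conf.fnr,
        confusion=conf,
        n=len(pred),
        cutoff_used=used_cutoff,
    )
    return {
        "ranking": ranking,
        "model": model,
        "scores": scores,
        "pred": pred,
        "adjustment": adjustment,
        "report": report,
        "per_repeat_auc": aucs,
    }


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: v for k, v in asdict(config).items()}, sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_end_to_end(config: RunConfig) -> Path:
    """File-based full pipeline run; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    source = load_domain_dataset(
        config.source_expr, config.source_resp, "source", max_conc=config.max_conc
    )
    target = load_domain_dataset(config.target_expr, config.target_resp, "target")
    source, target = preprocess_pair(
        source,
        target,
        hk_gene=config.hk_gene,
        hk_on_target=config.hk_on_target,
        harmonize=config.harmonize,
    )
    training = config.training or TrainingConfig(
        seed=config.seed, repeats=config.repeats
    )
    result = run_core(
        source,
        target,
        alpha=config.alpha,
        method=config.method,
        max_genes=config.max_genes,
        use_da=config.use_da,
        adjust_cutoff=config.adjust_cutoff,
        cutoff=config.cutoff,
        training=training,
        outer_repeats=config.outer_repeats,
    )

    result["ranking"].to_frame().to_csv(out / "ranking.tsv", sep="\t", index=False)
    result["model"].to_json(out / "model.json")
    pd.DataFrame(
        {
            "sample_id": target.expr.sample_ids,
            "score": result["scores"],
            "label": result["pred"],
        }
    ).to_csv(out / "predictions.tsv", sep="\t", index=False)
    report = result["report"].to_dict()
    report["n_passed_da"] = result["ranking"].n_passed_da
    if result["adjustment"] is not None:
        report["cutoff_adjustment"] = result["adjustment"].to_dict()
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    manifest = {
        "cl2pt_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": _config_hash(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1, default=str))
    return out


def alpha_sweep(
    source: DomainDataset,
    target: DomainDataset,
    alphas: tuple[float, ...] = (0.6, 0.7, 0.8, 0.9),
    **kwargs,
) -> pd.DataFrame:
    """Run the pipeline at several DA stringencies; one row per alpha."""
    rows = []
    for a in alphas:
        res = run_core(source, target, alpha=a, **kwargs)
        rows.append(
            {
                "alpha": a,
                "n_passed_da": res["ranking"].n_passed_da,
                "auc": res["report"].auc_mean,
                "accuracy": res["report"].accuracy,
            }
        )
    return pd.DataFrame(rows)


def ablation_compare(
    sim_config: SyntheticConfig,
    n_seeds: int = 10,
    alpha: float = 0.7,
    method: Literal["logitda", "knnda"] = "logitda",
    training: TrainingConfig | None = None,
    max_genes: int = 1000,
) -> dict:
    """Paired with-DA vs without-DA comparison on freshly simulated pairs.

    Both arms of each seed share the identical simulated data and CV seed
    (hence identical fold assignments), isolating the effect of the DA
    filter.  Returns per-seed AUCs, paired differences and their mean/s.e.
    """
    training = training or TrainingConfig()
    with_da, without_da = [], []
    for s in range(n_seeds):
        cfg = SyntheticConfig(**{**asdict(sim_config), "seed": sim_config.seed + s})
        source, target, _ = generate_domain_pair(cfg)
        tcfg = TrainingConfig(**{**asdict(training), "seed": training.seed + s})
        for use_da, sink in ((True, with_da), (False, without_da)):
            res = run_core(
                source,
                target,
                alpha=alpha,
                method=method,
                max_genes=max_genes,
                use_da=use_da,
                adjust_cutoff=False,
                training=tcfg,
            )
            sink.append(res["report"].auc_mean)
    diffs = np.array(with_da) - np.array(without_da)
    mean, se = repeat_summary(diffs) if n_seeds >= 2 else (float(diffs[0]), 0.0)
    return {
        "auc_with_da": with_da,
        "auc_without_da": without_da,
        "paired_diff": diffs.tolist(),
        "diff_mean": mean,
        "diff_se": se,
    }
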