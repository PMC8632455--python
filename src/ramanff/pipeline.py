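"""End-to-end orchestration: generate -> preprocess -> discover / classify.

A :class:`PipelineConfig` carries every stage's parameters plus one seed
that determines all randomness (cohort generation, splits, network
training). Reports are JSON plus CSV; every output embeds a hash of the
configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from ramanff.classify import (
    ANNConfig,
    confusion_and_report,
    five_fold_cv,
    loocv,
    predict_proba,
    roc_curve_auc,
    split_train_test,
    train_ann,
)
from ramanff.errors import ValidationError
from ramanff.preprocess import PreprocessConfig, mean_center, preprocess_set
from ramanff.spectra import (
    POSITIVE_CLASS,
    SpectrumSet,
    TASKS,
    read_dataset_manifest,
    write_dataset_manifest,
)
from ramanff.synthetic import SyntheticConfig, calibrated_config, generate_dataset
from ramanff.zones import loading_extrema, pca_decompose, scan_zones, group_difference_report

log = logging.getLogger("ramanff")

MODES = ("holdout", "loocv", "cv5")


@dataclass
class PipelineConfig:
    """Everything one run needs; ``seed`` feeds every stochastic stage."""

    task: str = "pcos"
    mode: str = "holdout"
    seed: int = 0
    out_dir: str = "ramanff_out"
    manifest: str | None = None  # None -> calibrated synthetic cohort
    n_per_group: int | tuple[int, int] | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    min_prominence: float = 0.08
    min_width: float = 30.0
    max_zones: int = 2
    n_components: int = 3
    ann: ANNConfig = field(default_factory=ANNConfig)
    train_per_class: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d and isinstance(d["preprocess"], dict):
            pp = dict(d["preprocess"])
            if "fingerprint" in pp:
                pp["fingerprint"] = tuple(pp["fingerprint"])
            d["preprocess"] = PreprocessConfig(**pp)
        if "ann" in d and isinstance(d["ann"], dict):
            ann = dict(d["ann"])
            if "hidden_sizes" in ann:
                ann["hidden_sizes"] = tuple(ann["hidden_sizes"])
            d["ann"] = ANNConfig(**ann)
        if isinstance(d.get("n_per_group"), list):
            d["n_per_group"] = tuple(d["n_per_group"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_or_generate(config: PipelineConfig) -> tuple[SpectrumSet, SyntheticConfig | None]:
    if config.manifest is not None:
        log.info("loading dataset manifest %s", config.manifest)
        return read_dataset_manifest(config.manifest), None
    overrides = {}
    if config.n_per_group is not None:
        overrides["n_per_group"] = config.n_per_group
    syn = calibrated_config(config.task, seed=config.seed, **overrides)
    log.info(
        "generating calibrated synthetic %s cohort (groups %s, seed %d)",
        config.task, syn.group_sizes, config.seed,
    )
    return generate_dataset(syn, config.task), syn


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_discovery(config: PipelineConfig) -> dict:
    """Discovery path: mean spectra, mean-centering, PCA, zone scan, stats.

    Writes ``report.json`` and ``quantifications.csv`` under
    ``config.out_dir`` and returns the report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, syn = _load_or_generate(config)
    log.info("preprocessing %d samples (discovery path, no denoising)", dataset.n_samples)
    pp = preprocess_set(dataset, config.preprocess, denoise=False)
    labels = pp.labels(config.task)
    w = pp.grid.wavenumbers
    mat = pp.intensity_matrix()

    group_mean_sd = {}
    for lab in np.unique(labels[labels != "NA"]):
        sel = mat[labels == lab]
        group_mean_sd[str(lab)] = {"mean": sel.mean(axis=0), "sd": sel.std(axis=0, ddof=1)}
    _, centered_group_means = mean_center(pp)

    n_comp = min(config.n_components, pp.n_samples - 1, mat.shape[1])
    log.info("PCA with %d components", n_comp)
    pca = pca_decompose(mat, n_comp, w)
    anchors = loading_extrema(pca, 0, config.min_prominence)
    log.info("loading anchors: %s", np.round(anchors, 1).tolist())
    stats = scan_zones(
        pp, labels, anchors, min_width=config.min_width, max_zones=config.max_zones
    )
    zones = [s.zone for s in stats]
    if zones:
        stats, per_sample = group_difference_report(pp, labels, zones)
    else:
        per_sample = {"labels": labels}

    report = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "task": config.task,
        "n_samples": pp.n_samples,
        "explained_variance_fraction": pca.explained_variance_fraction,
        "loading_anchors": anchors,
        "zones": [
            {
                "lo": s.zone.lo, "hi": s.zone.hi,
                "mean_pos": s.mean_pos, "mean_neg": s.mean_neg,
                "sd_pos": s.sd_pos, "sd_neg": s.sd_neg,
                "t_stat": s.t_stat, "p_value": s.p_value,
                "n_pos": s.n_pos, "n_neg": s.n_neg,
            }
            for s in stats
        ],
        "centered_group_means": centered_group_means,
    }
    (out / "report.json").write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True))

    import csv

    with open(out / "quantifications.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        zone_keys = [k for k in per_sample if k != "labels"]
        writer.writerow(["sample_id", "label", *zone_keys])
        kept = [m.sample_id for m, lab in zip(pp.samples, labels) if lab != "NA"]
        for i, sid in enumerate(kept):
            writer.writerow(
                [sid, per_sample["labels"][i], *(repr(float(per_sample[k][i])) for k in zone_keys)]
            )
    log.info("discovery report written to %s", out)
    return report


def run_classification(config: PipelineConfig) -> dict:
    """Classification path: preprocess with denoising, train, evaluate.

    Mode ``holdout`` reports a confusion matrix, per-class metrics and the
    test-set ROC; ``loocv`` and ``cv5`` report their respective summaries.
    Writes ``metrics.json`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, _ = _load_or_generate(config)
    log.info("preprocessing %d samples (classification path, %s denoising)",
             dataset.n_samples, config.preprocess.wavelet_family)
    pp = preprocess_set(dataset, config.preprocess, denoise=True)
    ann = dataclasses.replace(config.ann, seed=config.seed)
    pos = POSITIVE_CLASS[config.task]
    metrics: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "task": config.task,
        "mode": config.mode,
        "positive_class": pos,
    }
    if config.mode == "holdout":
        train, test = split_train_test(
            pp, config.task, seed=config.seed, train_per_class=config.train_per_class
        )
        log.info("holdout split: %d train / %d test", train.n_samples, test.n_samples)
        model = train_ann(train, ann, config.task)
        probs = predict_proba(model, test)[:, 1]
        y_true = test.labels(config.task)
        y_pred = np.where(probs >= 0.5, model.classes[1], model.classes[0])
        cm, report = confusion_and_report(y_true, y_pred, pos)
        roc_points, auc_val = roc_curve_auc((y_true == pos).astype(int), probs)
        metrics.update(
            confusion_matrix={"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
            class_report={"per_class": report.per_class, "accuracy": report.accuracy},
            roc={"points": roc_points, "auc": auc_val},
            final_train_loss=model.training_history[-1],
        )
    elif config.mode == "loocv":
        res = loocv(pp, ann, config.task)
        y_true = pp.labels(config.task)
        cm, report = confusion_and_report(y_true, res["predicted"], pos)
        metrics.update(
            loocv_accuracy=res["accuracy"],
            confusion_matrix={"tp": cm.tp, "fn": cm.fn, "fp": cm.fp, "tn": cm.tn},
            class_report={"per_class": report.per_class, "accuracy": report.accuracy},
        )
    else:  # cv5
        summary = five_fold_cv(pp, ann, config.task)
        metrics.update(cv_summary=dataclasses.asdict(summary))
    (out / "metrics.json").write_text(json.dumps(_jsonable(metrics), indent=2, sort_keys=True))
    log.info("classification metrics written to %s", out)
    return metrics


def run_generate(config: PipelineConfig) -> Path:
    """Generate a calibrated synthetic cohort and write it as CSV + manifest."""
    out = Path(config.out_dir)
    dataset, syn = _load_or_generate(config)
    manifest = write_dataset_manifest(dataset, out)
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "task": config.task,
        "synthetic_config": None if syn is None else _jsonable(dataclasses.asdict(syn)),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    log.info("cohort written to %s", out)
    return manifest
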