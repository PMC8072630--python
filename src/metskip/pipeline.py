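"""End-to-end orchestration: simulate -> subsample -> featurize -> train -> evaluate.

A run directory receives the exact configuration and per-stage seeds that
produced it, a feature matrix per split, the trained model bundle, and an
evaluation report.  Stages are idempotent: each records a hash of the
configuration slice it depends on, and a rerun skips stages whose hash and
outputs are intact (deleting a stage's outputs re-executes it and
everything downstream).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import datasets, evaluation, featurization, nets, simulate, subsampling
from .errors import DataError
from .gene_model import GeneModel, GenomicInterval, load_gene_model

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a reproducible run needs; serialized into the run directory."""

    outdir: str = "metskip_run"
    # gene model: synthetic fixture by default, or annotation + genome paths
    gene_seed: int = 20210419
    annotation: str | None = None
    genome: str | None = None
    gene_id: str = "MET"
    transcript_id: str = "MET-synthetic-201"
    locus: str | None = None  # 1-based inclusive chrom:start-end override
    skip_exon: int = 14
    scope: tuple[int, ...] = (13, 14, 15)
    # features
    feature_kind: str = "coverage_freq"
    k: int = 16
    include_skip_junction: bool = True
    # sampling / simulation
    group_size: int = 1000
    n_train_groups: int = 100  # per class
    n_test_groups: int = 30  # per class
    read_length: int = 150
    fragment_mean: float = 350.0
    fragment_sd: float = 50.0
    error_rate: float = 0.001
    # model
    arch: str = "nn"  # nn | cnn
    kernel_size: int = 100
    epochs: int = 50
    batch_size: int = 32
    val_fraction: float = 0.2
    threshold: float = 0.5
    seed: int = 7

    def __post_init__(self) -> None:
        self.scope = tuple(self.scope)
        if self.feature_kind not in featurization.FEATURE_KINDS:
            raise DataError(f"unknown feature kind {self.feature_kind!r}")
        if self.arch not in ("nn", "cnn"):
            raise DataError("arch must be 'nn' or 'cnn'")
        if (self.annotation is None) != (self.genome is None):
            raise DataError("annotation and genome must be given together")
        if not 0 < self.threshold < 1:
            raise DataError("threshold must be in (0, 1)")

    @property
    def seeds(self) -> dict[str, int]:
        """Per-stage seeds derived from the master seed."""
        return {
            "simulate_train_WT": self.seed * 10 + 1,
            "simulate_train_delta14": self.seed * 10 + 2,
            "simulate_test_WT": self.seed * 10 + 3,
            "simulate_test_delta14": self.seed * 10 + 4,
            "partition": self.seed * 10 + 5,
            "train": self.seed * 10 + 6,
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.pop("derived_seeds", None)
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["scope"] = list(self.scope)
        payload["derived_seeds"] = self.seeds
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _digest(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage_fresh(stage_file: Path, h: str, outputs: list[Path]) -> bool:
    if not stage_file.exists():
        return False
    try:
        recorded = json.loads(stage_file.read_text())["hash"]
    except (json.JSONDecodeError, KeyError):
        return False
    return recorded == h and all(p.exists() for p in outputs)


def load_configured_gene_model(cfg: RunConfig) -> GeneModel:
    locus = GenomicInterval.from_region_string(cfg.locus) if cfg.locus else None
    if cfg.annotation:
        return load_gene_model(cfg.annotation, cfg.genome, cfg.gene_id, cfg.transcript_id, locus)
    return datasets.synthetic_met_gene_model(cfg.gene_seed)


def _featurize_groups(groups, model, cfg: RunConfig, vocab):
    fvs = []
    for g in groups:
        if cfg.feature_kind.startswith("kmer"):
            fv = featurization.kmer_features(g, vocab)
        else:
            fv = featurization.coverage_features(g, model, cfg.scope)
        if cfg.feature_kind.endswith("_freq"):
            fv = featurization.to_frequency(fv)
        fvs.append(fv)
    return fvs


def build_split(
    model: GeneModel,
    cfg: RunConfig,
    split: str,
    vocab,
) -> tuple[list[featurization.FeatureVector], list[str]]:
    """Simulate both classes for one split and featurize the read groups."""
    n_groups = cfg.n_train_groups if split == "train" else cfg.n_test_groups
    fvs, labels = [], []
    for label in ("WT", "delta14"):
        sim_cfg = simulate.SimConfig(
            n_read_pairs=max(1, n_groups * cfg.group_size // 2),
            read_length=cfg.read_length,
            fragment_mean=cfg.fragment_mean,
            fragment_sd=cfg.fragment_sd,
            error_rate=cfg.error_rate,
            seed=cfg.seeds[f"simulate_{split}_{label}"],
        )
        specs = simulate.build_transcript_specs(model, label, skip_exon=cfg.skip_exon)
        rs = simulate.simulate_reads(specs, sim_cfg, sample_id=f"{split}_{label}")
        groups = subsampling.partition_reads(
            rs, cfg.group_size, seed=cfg.seeds["partition"], label=label
        )[:n_groups]
        split_fvs = _featurize_groups(groups, model, cfg, vocab)
        fvs.extend(split_fvs)
        labels.extend([label] * len(split_fvs))
    return fvs, labels


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full pipeline into ``cfg.outdir``; returns the run dir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")
    model = load_configured_gene_model(cfg)

    vocab = None
    if cfg.feature_kind.startswith("kmer"):
        vocab = featurization.build_vocabulary(
            model, cfg.k, cfg.scope, cfg.include_skip_junction, cfg.skip_exon
        )
    schema = featurization.feature_schema(
        cfg.feature_kind,
        cfg.scope,
        len(vocab) if vocab else sum(len(model.exon(o)) for o in cfg.scope),
        k=cfg.k if vocab else None,
        vocabulary_hash=vocab.hash if vocab else None,
    )
    schema_hash = featurization.schema_digest(schema)

    # ---- stage: features -------------------------------------------------
    feat_cfg = {
        k: v
        for k, v in asdict(cfg).items()
        if k not in ("outdir", "arch", "kernel_size", "epochs", "batch_size", "val_fraction", "threshold")
    }
    feat_hash = _digest(feat_cfg)
    feat_outputs = [outdir / "train.tsv", outdir / "test.tsv"]
    forced = False
    if not _stage_fresh(outdir / "features.done.json", feat_hash, feat_outputs):
        logger.info("stage features: building train/test matrices")
        for split, path in zip(("train", "test"), feat_outputs):
            fvs, labels = build_split(model, cfg, split, vocab)
            featurization.write_feature_matrix(fvs, path, schema, labels)
        (outdir / "features.done.json").write_text(json.dumps({"hash": feat_hash}))
        forced = True
    else:
        logger.info("stage features: up to date, skipped")

    # ---- stage: train ----------------------------------------------------
    train_hash = _digest({"features": feat_hash, "arch": cfg.arch, "kernel": cfg.kernel_size,
                          "epochs": cfg.epochs, "batch": cfg.batch_size,
                          "val_fraction": cfg.val_fraction, "seed": cfg.seeds["train"]})
    model_path = outdir / "model.npz"
    if forced or not _stage_fresh(outdir / "train.done.json", train_hash, [model_path]):
        logger.info("stage train: fitting %s", cfg.arch)
        _ids, X, labels, _schema = featurization.load_feature_matrix(outdir / "train.tsv")
        spec = (
            nets.DenseNetSpec(input_dim=X.shape[1])
            if cfg.arch == "nn"
            else nets.ConvNetSpec(input_dim=X.shape[1], kernel_size=cfg.kernel_size)
        )
        tm = nets.train_classifier(
            spec,
            X,
            labels,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            val_fraction=cfg.val_fraction,
            seed=cfg.seeds["train"],
            feature_schema_hash=schema_hash,
        )
        nets.save_model(tm, model_path)
        (outdir / "train.done.json").write_text(json.dumps({"hash": train_hash}))
        forced = True
    else:
        logger.info("stage train: up to date, skipped")

    # ---- stage: evaluate -------------------------------------------------
    eval_hash = _digest({"train": train_hash, "threshold": cfg.threshold})
    report_path = outdir / "report.json"
    if forced or not _stage_fresh(outdir / "evaluate.done.json", eval_hash, [report_path]):
        logger.info("stage evaluate: scoring held-out groups")
        tm = nets.load_model(model_path)
        _ids, Xt, labels_t, _schema = featurization.load_feature_matrix(outdir / "test.tsv")
        scores = nets.predict(tm, Xt, schema_hash=schema_hash)
        roc_res = evaluation.roc(scores, labels_t)
        calls = nets.classify(tm, Xt, threshold=cfg.threshold)
        cs = evaluation.ConfusionSummary.from_calls(labels_t, calls)
        report = {
            "auc": roc_res.auc,
            "confusion": {
                "total": cs.total,
                "positives": cs.positives,
                "predicted_positive": cs.predicted_positive,
                "true_positive": cs.true_positive,
                "false_positive": cs.false_positive,
            },
            "sensitivity_pct": evaluation.sensitivity_pct(cs),
            "specificity_overall_pct": evaluation.specificity_overall_pct(cs),
            "specificity_classical_pct": evaluation.specificity_classical_pct(cs),
            "threshold": cfg.threshold,
            "feature_schema": schema,
        }
        report_path.write_text(json.dumps(report, indent=2))
        np.savetxt(
            outdir / "roc.tsv",
            np.column_stack([roc_res.fpr, roc_res.tpr]),
            header="fpr\ttpr",
            delimiter="\t",
            comments="",
            fmt="%.10g",
        )
        (outdir / "evaluate.done.json").write_text(json.dumps({"hash": eval_hash}))
    else:
        logger.info("stage evaluate: up to date, skipped")
    return outdir
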