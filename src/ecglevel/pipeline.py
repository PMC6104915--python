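"""End-to-end pipeline: simulate -> delineate -> fit -> predict -> report.

Each stage consumes and produces on-disk artifacts (a cohort bundle, a
delineation CSV, model artifact files, a report directory), so running the
stages individually through the CLI and running :func:`run_pipeline` are
the same computation.  A manifest records the configuration, seeds and
package version for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_gen import generate_cohort
from .delineation import delineate_cohort
from .errors import ConfigError
from .evaluation import build_report, split_cohort, write_report
from .io import read_cohort_bundle, read_ground_truth, write_cohort_bundle
from .linear import LinearModelArtifact, fit_linear
from .nn import (DeepModelArtifact, NetworkConfig, TrainConfig,
                 demo_network_config, train)


@dataclass
class RunConfig:
    """Full pipeline configuration; every stochastic stage has an explicit seed."""

    n_subjects: int = 8
    protocol: str = "A"
    effect_config: str = "duration_plus_morphology"
    arm_fractions: dict | None = None
    noise_uv: float = 6.0
    generator_seed: int | None = None

    network: str | dict = "demo"     # "demo", "default", or NetworkConfig kwargs
    epochs: int = 12
    learning_rate: float = 3e-3
    batch_size: int = 64
    train_seed: int | None = None
    train_deep: bool = True

    clip_negative: bool = False
    outdir: str = "pipeline_out"

    def validate(self) -> None:
        if self.generator_seed is None:
            raise ConfigError("generator_seed must be set explicitly")
        if self.train_deep and self.train_seed is None:
            raise ConfigError("train_seed must be set explicitly")
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be at least 2")
        self.network_config()  # raises on malformed network section

    def network_config(self) -> NetworkConfig:
        if self.network == "demo":
            return demo_network_config()
        if self.network == "default":
            return NetworkConfig()
        if isinstance(self.network, dict):
            return NetworkConfig(**{k: tuple(v) if isinstance(v, list) else v
                                    for k, v in self.network.items()})
        raise ConfigError(f"unknown network spec {self.network!r}")

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages (on-disk interfaces)


def stage_simulate(config: RunConfig, outdir: Path) -> Path:
    cohort, truth = generate_cohort(
        config.n_subjects, protocol=config.protocol,
        arm_fractions=config.arm_fractions, master_seed=config.generator_seed,
        effect_config=config.effect_config, noise_uv=config.noise_uv)
    cohort_dir = outdir / "cohort"
    write_cohort_bundle(cohort, cohort_dir, ground_truth=truth.table)
    return cohort_dir


def stage_delineate(cohort_dir: Path, out_csv: Path) -> Path:
    cohort = read_cohort_bundle(cohort_dir)
    delineate_cohort(cohort).to_csv(out_csv, index=False)
    return out_csv


def stage_train(config: RunConfig, cohort_dir: Path, delineation_csv: Path,
                models_dir: Path) -> Path:
    cohort = read_cohort_bundle(cohort_dir)
    delin = pd.read_csv(delineation_csv)
    train_ids, test_ids = split_cohort(cohort)
    models_dir.mkdir(parents=True, exist_ok=True)
    (models_dir / "split.json").write_text(json.dumps(
        {"train": train_ids, "test": test_ids}, indent=2) + "\n")

    conc = {(s.subject_id, s.timepoint_h): s.concentration_pg_ml
            for s in cohort.samples}
    pairs = [(row.qtc_bazett_ms, conc[(row.subject_id, row.timepoint_h)])
             for _, row in delin.iterrows()
             if row.subject_id in set(train_ids)
             and np.isfinite(row.qtc_bazett_ms)]
    linear = fit_linear(pairs, train_subject_ids=train_ids)
    linear.to_json(models_dir / "linear_model.json")

    if config.train_deep:
        samples = [(rec, s.concentration_pg_ml) for s in cohort.samples
                   if s.subject_id in set(train_ids) for rec in s.replicates]
        artifact = train(samples, config.network_config(),
                         TrainConfig(learning_rate=config.learning_rate,
                                     epochs=config.epochs,
                                     batch_size=config.batch_size,
                                     seed=config.train_seed))
        artifact.save(models_dir / "deep_model")
    return models_dir


def stage_evaluate(config: RunConfig, cohort_dir: Path, delineation_csv: Path,
                   models_dir: Path, report_dir: Path) -> Path:
    cohort = read_cohort_bundle(cohort_dir)
    delin = pd.read_csv(delineation_csv)
    split = json.loads((models_dir / "split.json").read_text())
    linear = LinearModelArtifact.from_json(models_dir / "linear_model.json")
    deep = None
    if (models_dir / "deep_model").exists():
        deep = DeepModelArtifact.load(models_dir / "deep_model")
    test = cohort.subset(split["test"])
    report = build_report(
        test, delin[delin.subject_id.isin(split["test"])],
        linear_artifact=linear, deep_artifact=deep,
        clip_negative=config.clip_negative,
        metadata={"config_hash": _config_hash(config),
                  "n_train_subjects": len(split["train"]),
                  "n_test_subjects": len(split["test"])})
    write_report(report, report_dir)
    truth = read_ground_truth(cohort_dir)
    if truth is not None:
        truth[truth.subject_id.isin(split["test"])].to_csv(
            report_dir / "ground_truth_test.csv", index=False)
    return report_dir


def run_pipeline(config: RunConfig):
    """Run all stages; returns the :class:`~ecglevel.evaluation.EvaluationReport`.

    The output directory is laid out deterministically::

        outdir/
          manifest.json
          cohort/            # bundle + ground_truth.csv
          delineation.csv
          models/            # split.json, linear_model.json, deep_model/
          report/            # report.json, pairs.csv, qtc_table.csv, ...
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "python": platform.python_version(),
        "stages": [],
    }
    try:
        cohort_dir = stage_simulate(config, outdir)
        manifest["stages"].append("simulate")
        delin_csv = stage_delineate(cohort_dir, outdir / "delineation.csv")
        manifest["stages"].append("delineate")
        models_dir = stage_train(config, cohort_dir, delin_csv,
                                 outdir / "models")
        manifest["stages"].append("train")
        report_dir = stage_evaluate(config, cohort_dir, delin_csv, models_dir,
                                    outdir / "report")
        manifest["stages"].append("evaluate")
    except Exception:
        (outdir / "FAILED").write_text(
            f"pipeline failed after stages {manifest['stages']}\n")
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str) + "\n")
    from .evaluation import EvaluationReport  # local import to avoid cycles
    metrics = json.loads((report_dir / "report.json").read_text())
    return EvaluationReport(
        pairs=pd.read_csv(report_dir / "pairs.csv"),
        metrics=metrics["metrics"],
        qtc_table=pd.read_csv(report_dir / "qtc_table.csv"),
        timecourse=pd.read_csv(report_dir / "timecourse.csv"),
        metadata=metrics["metadata"],
    )
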