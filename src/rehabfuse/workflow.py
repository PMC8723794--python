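"""Experiment configuration and end-to-end orchestration.

An :class:`ExperimentConfig` ties together the synthetic cohort settings,
the signal/feature registry, the GPR and fusion settings and the global
seed; :func:`run_experiment` runs simulate -> process -> featurize ->
LOSOCV -> report and writes the artifacts (each stamped with the config
hash and seed) to an output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .estimators import GPRConfig
from .evaluation import EvaluationReport, LosocvConfig, run_losocv
from .features import FeatureRegistry, build_feature_tables
from .synthgen import (CohortConfig, RecordingConfig, SyntheticDataset,
                       generate_dataset, read_dataset, write_dataset)

__all__ = ["ExperimentConfig", "run_experiment", "load_config", "config_hash"]

logger = logging.getLogger("rehabfuse")


class ConfigError(ValueError):
    """Raised for invalid or inconsistent experiment configuration."""


@dataclass
class ExperimentConfig:
    """Full, explicit configuration of one experiment."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    recording: RecordingConfig = field(default_factory=RecordingConfig)
    registry: FeatureRegistry = field(default_factory=FeatureRegistry)
    losocv: LosocvConfig = field(default_factory=LosocvConfig)
    n_repetitions: int = 3
    seed: int = 0
    data_dir: str | None = None     # load a written dataset instead of simulating

    def validate(self) -> None:
        self.cohort.validate()
        if self.n_repetitions < 1:
            raise ConfigError("n_repetitions must be >= 1")
        if self.recording.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")


def _from_mapping(cls, data: dict):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown {cls.__name__} field: {key!r}")
        ftype = fields[key].type
        if isinstance(value, dict):
            sub = {"cohort": CohortConfig, "recording": RecordingConfig,
                   "registry": FeatureRegistry, "losocv": LosocvConfig,
                   "gpr_sensor": GPRConfig, "gpr_clinical": GPRConfig}.get(key)
            value = _from_mapping(sub, value) if sub else value
        elif isinstance(value, list):
            value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
        kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from YAML."""
    try:
        data = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    cfg = _from_mapping(ExperimentConfig, data)
    cfg.validate()
    return cfg


def config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(config: ExperimentConfig,
                   out_dir: str | Path | None = None,
                   dataset: SyntheticDataset | None = None) -> EvaluationReport:
    """Run the full pipeline and (optionally) persist artifacts.

    Stages: simulate (or load) the dataset, extract features, run the
    leave-one-subject-out evaluation, and write the report. Idempotent
    given the seed; per-stage wall times are logged to stderr.
    """
    config.validate()
    chash = config_hash(config)
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if dataset is None:
            if config.data_dir:
                dataset = read_dataset(config.data_dir)
            else:
                dataset = generate_dataset(config.cohort, config.recording,
                                           seed=config.seed,
                                           n_repetitions=config.n_repetitions)
        logger.info("stage=%s elapsed=%.1fs", stage, time.perf_counter() - t0)

        stage = "featurize"
        t0 = time.perf_counter()
        tables = build_feature_tables(dataset, config.registry)
        logger.info("stage=%s elapsed=%.1fs", stage, time.perf_counter() - t0)

        stage = "evaluate"
        t0 = time.perf_counter()
        report = run_losocv(dataset, tables, config.losocv,
                            registry=config.registry, seed=config.seed)
        report.config_hash = chash
        logger.info("stage=%s elapsed=%.1fs", stage, time.perf_counter() - t0)
    except Exception as exc:
        raise RuntimeError(f"experiment failed in stage {stage!r}: {exc}") from exc

    if out_dir is not None:
        report.save(out_dir)
        meta = {"config_hash": chash, "seed": config.seed,
                "config": dataclasses.asdict(config)}
        Path(out_dir, "experiment.json").write_text(
            json.dumps(meta, indent=1, default=str))
    return report
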