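"""End-to-end orchestration of the screening study on synthetic cohorts.

The stage order mirrors the clinical processing chain: simulate (or
load) recordings, clean both channels and gate on usable duration,
extract the 38-feature battery, select features per data source with
bootstrap FCBF, tune and train one support-vector regressor per source
(oximetry only, airflow only, dual channel), and evaluate agreement and
diagnostic performance of the estimated AHI on the held-out,
chronologically later part of the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .evaluation import DiagnosticReport, build_report, icc_agreement
from .features import FeatureTable, build_feature_table
from .preprocess import preprocess_recording
from .regression import (
    DEFAULT_EPSILON,
    HyperParams,
    fit,
    hyperparameter_grid,
    predict,
    tune,
)
from .selection import SelectionResult, bootstrap_fcbf
from .signals import Recording, split_train_test
from .simulate import STUDY_SEVERITY_MIX, SimulationConfig, simulate_cohort

logger = logging.getLogger("oxyflow")

__all__ = ["PipelineConfig", "StudyResult", "run_screening_study", "channel_columns"]

MODEL_CHANNELS = {"spo2": ("spo2",), "airflow": ("af",), "dual": ("spo2", "af")}


@dataclass
class PipelineConfig:
    """One document of every stage's tunables (YAML-loadable)."""

    n_recordings: int = 160
    train_fraction: float = 0.6
    ahi_law: tuple = ("mixture", STUDY_SEVERITY_MIX)
    simulator: SimulationConfig = field(default_factory=SimulationConfig)
    min_valid_hours: float = 4.0
    selection_B: int = 1000
    epsilon: float = DEFAULT_EPSILON
    eval_B: int = 1000
    seed: int = 0
    models: tuple = ("spo2", "airflow", "dual")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulator", {}))
        if "ahi_law" in raw:
            law = raw["ahi_law"]
            raw["ahi_law"] = tuple(law) if isinstance(law, (list, tuple)) else law
        return cls(simulator=sim, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


@dataclass
class StudyResult:
    """Everything the full study produces, JSON-serialisable."""

    models: dict
    report: DiagnosticReport
    test_reference_ahi: list
    n_train: int
    n_test: int
    n_rejected: int

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "report": self.report.to_dict(),
            "test_reference_ahi": self.test_reference_ahi,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "n_rejected": self.n_rejected,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def channel_columns(table: FeatureTable, channels: tuple[str, ...]) -> list[str]:
    """Feature columns belonging to the given channel prefixes."""
    prefixes = tuple(f"{c}_" for c in channels)
    return [name for name in table.feature_names if name.startswith(prefixes)]


def preprocess_cohort(
    records: list[Recording], min_hours: float
) -> tuple[list[Recording], int]:
    """Clean every recording, dropping those failing the duration gate."""
    kept = []
    rejected = 0
    for rec in records:
        cleaned, report = preprocess_recording(rec, min_hours=min_hours)
        if report.accepted:
            kept.append(cleaned)
        else:
            rejected += 1
            logger.info("rejected %s: %s", rec.id, report.post_duration_h)
    return kept, rejected


def _fit_one_model(
    name: str,
    train: FeatureTable,
    test: FeatureTable,
    config: PipelineConfig,
    grid: list[HyperParams] | None,
) -> tuple[dict, np.ndarray]:
    columns = channel_columns(train, MODEL_CHANNELS[name])
    selection: SelectionResult = bootstrap_fcbf(
        train.subset(columns), B=config.selection_B, seed=config.seed
    )
    selected = selection.selected
    if not selected:  # degenerate cohort: fall back to full relevance ranking
        logger.warning("%s: empty FCBF selection, using all %d features", name, len(columns))
        selected = columns
    hp, training_icc = tune(train, selected, grid=grid)
    model = fit(train, selected, hp, training_icc=training_icc)
    preds = predict(model, test)
    info = {
        "selection": selection.to_dict(),
        "selected_features": model.selected_features,
        "hp": {"C": hp.C, "sigma": hp.sigma, "epsilon": hp.epsilon},
        "training_icc": training_icc,
        "test_icc": icc_agreement(test.y.to_numpy(), preds),
        "predictions": preds.tolist(),
    }
    return info, preds


def run_screening_study(
    config: PipelineConfig,
    grid: list[HyperParams] | None = None,
    records: list[Recording] | None = None,
) -> StudyResult:
    """Run the whole study and return models, predictions and the report.

    ``records`` may supply pre-made (raw) recordings; otherwise a
    synthetic cohort is generated from ``config``.  The hyperparameter
    ``grid`` defaults to the full assessed grid.
    """
    if records is None:
        sims = simulate_cohort(
            config.n_recordings,
            ahi_law=config.ahi_law,
            cfg=config.simulator,
            seed=config.seed,
        )
        records = [s.recording for s in sims]
    cleaned, rejected = preprocess_cohort(records, config.min_valid_hours)
    if len(cleaned) < 6:
        raise ValueError("too few recordings survive preprocessing")
    table = build_feature_table(cleaned)
    train_rows, test_rows = split_train_test(
        np.arange(len(table)), config.train_fraction
    )
    train = table.rows(list(train_rows))
    test = table.rows(list(test_rows))
    if grid is None:
        grid = hyperparameter_grid(epsilon=config.epsilon)

    models = {}
    preds_per_model = {}
    for name in config.models:
        info, preds = _fit_one_model(name, train, test, config, grid)
        models[name] = info
        preds_per_model[name] = preds
        logger.info(
            "%s: %d features, C=%g sigma=%g, ICC train %.3f / test %.3f",
            name,
            len(info["selected_features"]),
            info["hp"]["C"],
            info["hp"]["sigma"],
            info["training_icc"],
            info["test_icc"],
        )
    actual = test.y.to_numpy(dtype=float)
    report = build_report(actual, preds_per_model, B=config.eval_B, seed=config.seed)
    return StudyResult(
        models=models,
        report=report,
        test_reference_ahi=actual.tolist(),
        n_train=len(train),
        n_test=len(test),
        n_rejected=rejected,
    )
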