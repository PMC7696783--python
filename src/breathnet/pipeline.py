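"""Umbrella experiment runner: simulate -> featurize -> cross-validate -> report.

A :class:`RunConfig` bundles the stage configurations with an experiment
preset pinning the cohort composition:

    exp1-all                     69 healthy + 52 cancer, no balancing
    exp2-lung                    69 healthy + 21 cancer, balanced to 21+21
    exp3-oropharyngeal-laryngeal 69 healthy + 31 cancer, balanced to 31+31

Per-stage seeds are derived from the master seed by fixed offsets so any
stage can be re-run in isolation; re-running an identical config reproduces
byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datasets import features_to_frame, load_dataset, write_dataset
from .evaluate import (CVConfig, DiagnosticReport, balance_dataset,
                       confusion_report, cross_validate, roc_curve,
                       save_roc_plot, scatter_report, select_threshold)
from .exceptions import ParameterError
from .mlp import NetworkConfig
from .preprocess import PreprocessConfig, featurize
from .simulate import SimulatorParams, simulate_cohort

logger = logging.getLogger("breathnet")

#: preset -> (n_healthy, n_cancer, balance)
EXPERIMENT_PRESETS = {
    "exp1-all": (69, 52, False),
    "exp2-lung": (69, 21, True),
    "exp3-oropharyngeal-laryngeal": (69, 31, True),
}

_STAGE_OFFSETS = {"simulate": 0, "balance": 1, "train": 2}


def stage_seed(master_seed: int, stage: str) -> int:
    state = np.random.SeedSequence(
        [int(master_seed), _STAGE_OFFSETS[stage]]).generate_state(1)
    return int(state[0]) % (2 ** 31)


@dataclass
class RunConfig:
    """Composite configuration of one end-to-end experiment."""

    simulator: SimulatorParams = field(default_factory=SimulatorParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    preset: str = "custom"
    n_healthy: int = 69
    n_cancer: int = 52
    balance: bool = False
    master_seed: int = 0
    out_root: str = "runs/experiment"
    persist_raw: bool = True
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.preset != "custom":
            if self.preset not in EXPERIMENT_PRESETS:
                raise ParameterError(
                    f"unknown preset {self.preset!r}; choose from "
                    f"{sorted(EXPERIMENT_PRESETS)} or 'custom'")
            self.n_healthy, self.n_cancer, self.balance = \
                EXPERIMENT_PRESETS[self.preset]

    def validate(self) -> None:
        self.simulator.validate()
        self.preprocess.validate()
        self.network.validate()
        self.cv.validate()

    # -- YAML round trip --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("baseline_per_sensor", "amplitude_per_sensor",
                    "class_effect"):
            d["simulator"][key] = [float(v) for v in d["simulator"][key]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("simulator", SimulatorParams),
                         ("preprocess", PreprocessConfig),
                         ("network", NetworkConfig), ("cv", CVConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def _config_hash(config: RunConfig) -> str:
    """Hash of the scientific configuration only; output paths and
    plotting/persistence switches do not change the result."""
    d = config.to_dict()
    for key in ("out_root", "persist_raw", "make_plots"):
        d.pop(key, None)
    payload = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_experiment(config: RunConfig) -> DiagnosticReport:
    """Execute the full pipeline and archive every intermediate artifact."""
    config.validate()
    out = Path(config.out_root)
    out.mkdir(parents=True, exist_ok=True)

    sim_seed = stage_seed(config.master_seed, "simulate")
    logger.info("simulating cohort: %d healthy + %d cancer (seed %d)",
                config.n_healthy, config.n_cancer, sim_seed)
    cohort = simulate_cohort(config.simulator, config.n_healthy,
                             config.n_cancer, sim_seed)
    if config.persist_raw:
        write_dataset(cohort, out / "data")
        cohort = load_dataset(out / "data")

    logger.info("featurizing %d subjects", len(cohort))
    features = [featurize(rec.recording, config.preprocess) for rec in cohort]
    features_to_frame(features).to_csv(out / "features.csv", index=False)

    if config.balance:
        features = balance_dataset(features,
                                   stage_seed(config.master_seed, "balance"))
        logger.info("balanced to %d subjects (50/50)", len(features))

    net_config = dataclasses.replace(
        config.network, seed=stage_seed(config.master_seed, "train"))
    cv_config = dataclasses.replace(
        config.cv, seed=stage_seed(config.master_seed, "train"))
    result = cross_validate(features, cv_config, net_config)
    result.to_frame().to_csv(out / "cv_scores.csv", index=False)

    roc = roc_curve(result)
    pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr,
                  "tpr": roc.tpr}).to_csv(out / "roc.csv", index=False)
    threshold = select_threshold(roc)
    report = confusion_report(result, threshold, auc=roc.auc)

    payload = {"report": report.as_dict(),
               "n_subjects": len(features),
               "preset": config.preset,
               "provenance": {
                   "config_hash": _config_hash(config),
                   "master_seed": config.master_seed,
                   "stage_seeds": {s: stage_seed(config.master_seed, s)
                                   for s in _STAGE_OFFSETS},
                   "breathnet_version": __version__,
               }}
    (out / "report.json").write_text(json.dumps(payload, indent=1,
                                                sort_keys=True))
    config.to_yaml(out / "config.yaml")
    if config.make_plots:
        scatter_report(result, threshold, path=str(out / "scatter.png"))
        save_roc_plot(roc, str(out / "roc.png"))
    logger.info("AUC %.3f, threshold %.3g, accuracy %.2f%%",
                roc.auc, threshold, report.accuracy)
    return report
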