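"""YAML configuration loading for studies.

A config file has optional blocks ``population``, ``pk``, ``covariates`` and
``study``; omitted fields fall back to the built-in docetaxel defaults.
Example::

    study:
      n_patients: 600
      variant: base
      seed: 2017
      scenarios: [baseline_only, baseline_day5, daily:7, daily:15]
    population:
      slope_typ: 15.6
    pk:
      exposure_scale: 1.0
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .pk import PKConfig
from .population import PopulationModel
from .simulate import CovariateConfig, Scenario
from .study import StudyConfig

__all__ = ["load_config", "default_config"]


def _build(cls, block: dict, label: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - valid
    if unknown:
        raise ValueError(f"unknown keys in {label} block: {sorted(unknown)}")
    coerced = {k: (tuple(v) if isinstance(v, list) else v) for k, v in block.items()}
    return cls(**coerced)


def load_config(path: str | Path) -> StudyConfig:
    """Load and validate a study configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    pop = _build(PopulationModel, raw.get("population", {}), "population")
    pk = _build(PKConfig, raw.get("pk", {}), "pk")
    cov = _build(CovariateConfig, raw.get("covariates", {}), "covariates")
    study = dict(raw.get("study", {}))
    if "scenarios" in study:
        study["scenarios"] = [Scenario.parse(s) for s in study["scenarios"]]
    cfg = _build(
        StudyConfig,
        {**study, "population": pop, "pk": pk, "covariates": cov},
        "study",
    )
    return cfg


def default_config() -> StudyConfig:
    return StudyConfig()
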