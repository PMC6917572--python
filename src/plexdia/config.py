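"""Run configuration: a single YAML file mirroring the pipeline blocks.

Unknown keys are rejected (typos fail loudly at load time). The
configuration hash — SHA-256 of the canonical JSON dump, truncated — is
stamped on every output table together with the seed for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .segment import SegmentationParams
from .synthdata import CohortConfig, ConfigurationError, DetectionModel

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class ScoringOptions:
    percentile: float = 11.0
    min_cells: int = 50
    chrom_markers: tuple[str, ...] = ("CDX2",)


@dataclass(frozen=True)
class StatsOptions:
    horizon_months: float = 60.0
    covariates: tuple[str, ...] = ()


@dataclass(frozen=True)
class RunConfig:
    output_dir: Path
    cohort: CohortConfig
    detection: DetectionModel = DetectionModel()
    segmentation: SegmentationParams = SegmentationParams()
    scoring: ScoringOptions = ScoringOptions()
    stats: StatsOptions = StatsOptions()

    @property
    def seed(self) -> int:
        return self.cohort.seed

    def hash(self) -> str:
        return config_hash(self)


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in '{name}' block: {sorted(unknown)}")
    coerced = {}
    for k, v in block.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    return cls(**coerced)


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from a YAML file, applying flat CLI overrides.

    Overrides use dotted keys (e.g. ``cohort.n_cases``); plain ``seed``,
    ``n_cases`` and ``min_cells`` shortcuts are also understood.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")

    shortcuts = {"seed": "cohort.seed", "n_cases": "cohort.n_cases", "min_cells": "scoring.min_cells"}
    for key, value in (overrides or {}).items():
        key = shortcuts.get(key, key)
        block, _, leaf = key.partition(".")
        if not leaf:
            raise ConfigurationError(f"override '{key}' must be 'block.key'")
        raw.setdefault(block, {})[leaf] = value

    known_blocks = {"output_dir", "cohort", "detection", "segmentation", "scoring", "stats"}
    unknown = set(raw) - known_blocks
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {sorted(unknown)}")
    if "cohort" not in raw or "n_cases" not in raw["cohort"]:
        raise ConfigurationError("config must set cohort.n_cases")

    return RunConfig(
        output_dir=Path(raw.get("output_dir", "plexdia_out")),
        cohort=_build(CohortConfig, raw.get("cohort", {}), "cohort"),
        detection=_build(DetectionModel, raw.get("detection", {}), "detection"),
        segmentation=_build(SegmentationParams, raw.get("segmentation", {}), "segmentation"),
        scoring=_build(ScoringOptions, raw.get("scoring", {}), "scoring"),
        stats=_build(StatsOptions, raw.get("stats", {}), "stats"),
    )


def _canonical(obj) -> object:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _canonical(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (tuple, list)):
        return [_canonical(v) for v in obj]
    return obj


def config_hash(config: RunConfig) -> str:
    """Short SHA-256 of the canonical JSON form of the configuration."""
    payload = json.dumps(_canonical(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
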