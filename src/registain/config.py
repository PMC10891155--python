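"""YAML run configuration: defaults, strict validation, snapshots.

Unknown keys are rejected with the offending key named; constraint
violations surface the dataclass' own error message (which names the field
and the constraint).  Every run can write a resolved-config snapshot that
reloads to an identical configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .evalqc import QCConfig
from .losses import LossConfig
from .phantom import ArtifactSpec, MisalignmentSpec, PhantomSpec
from .prep import ScreenConfig
from .trainer import TrainConfig


class ConfigError(ValueError):
    pass


@dataclass
class PrepOptions:
    tile: int = 3248
    crop: int = 2048
    tissue_min: float = 0.05
    angle_grid: tuple = (0.0, 90.0, 180.0, -90.0)
    refine_affine: bool = True

    def __post_init__(self):
        if self.tile <= 0 or self.crop <= 0 or self.crop > self.tile:
            raise ConfigError("require 0 < crop <= tile")


@dataclass
class InferOptions:
    tile: int = 2048
    overlap: int = 64

    def __post_init__(self):
        if not 0 <= self.overlap < self.tile:
            raise ConfigError("require 0 <= overlap < tile")


_SECTIONS = {
    "phantom": PhantomSpec,
    "artifact": ArtifactSpec,
    "misalignment": MisalignmentSpec,
    "prep": PrepOptions,
    "screen": ScreenConfig,
    "train": TrainConfig,
    "infer": InferOptions,
    "qc": QCConfig,
}
_NESTED = {"loss": LossConfig}


@dataclass
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "."
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    artifact: ArtifactSpec = field(default_factory=ArtifactSpec)
    misalignment: Optional[MisalignmentSpec] = None
    prep: PrepOptions = field(default_factory=PrepOptions)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    infer: InferOptions = field(default_factory=InferOptions)
    qc: QCConfig = field(default_factory=QCConfig)


def _build_dataclass(cls, data: dict, context: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"section '{context}' must be a mapping")
    allowed = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"unknown key '{context}.{key}'")
        if key in _NESTED and isinstance(value, dict):
            value = _build_dataclass(_NESTED[key], value, f"{context}.{key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section '{context}': {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; empty file means all defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("top-level configuration must be a mapping")
    kwargs = {}
    for key, value in data.items():
        if key in ("seed", "log_level", "output_dir"):
            kwargs[key] = value
        elif key in _SECTIONS:
            kwargs[key] = _build_dataclass(_SECTIONS[key], value, key)
        else:
            raise ConfigError(f"unknown key '{key}'")
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def save_snapshot(cfg: RunConfig, path) -> None:
    """Write the resolved configuration; reloading it reproduces the config."""
    data = _jsonable(cfg)
    # ndarray-valued defaults (stain vectors) are dropped from the snapshot —
    # they are code defaults, not user configuration; unset sections likewise
    if isinstance(data.get("qc"), dict):
        data["qc"].pop("stain_vectors", None)
    data = {k: v for k, v in data.items() if v is not None}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
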