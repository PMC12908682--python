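"""YAML configuration loading/validation and run manifests.

A config file may define any of the sections ``model``, ``train``,
``pipeline`` and ``synthetic``; omitted keys take the package defaults
(batch size 256, learning rate 1e-3, augmentation factor 20, ...).
Unknown keys are rejected with the offending names.  Every CLI run
writes exactly one JSON manifest capturing the resolved config, its
hash, the seed, the package version and the input/output paths.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .model import ModelConfig
from .synthetic import SyntheticSpec
from .training import TrainConfig

__version__ = "0.1.0"


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    test_fraction: float = 0.1
    val_fraction: float = 0.1
    augmentation_factor: int = 20
    max_shift: int = 100
    n_bins: int = 10
    coordinate_base: int = 0  # declare 1 for 1-based interval inputs
    seed: int = 0


class Config(BaseModel):
    model_config = ConfigDict(extra="forbid")

    model: ModelConfig = ModelConfig()
    train: TrainConfig = TrainConfig()
    pipeline: PipelineConfig = PipelineConfig()
    synthetic: SyntheticSpec = SyntheticSpec()


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a YAML config; ``None`` or an empty file gives
    all defaults.  Schema violations raise :class:`ConfigError` naming
    the offending keys."""
    raw = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return Config(**raw)
    except ValidationError as e:
        offenders = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in e.errors())
        raise ConfigError(f"invalid configuration keys/values: {offenders}") from e


def dump_config(config: Config) -> dict:
    """Fully resolved (normalized) config as plain data."""
    return config.model_dump()


def config_hash(config: Config) -> str:
    return hashlib.sha256(
        json.dumps(dump_config(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written once per CLI run."""

    command: str
    seed: int
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    finished: float | None = None
    version: str = __version__

    @property
    def config_digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def write(self, path: str | Path) -> Path:
        self.finished = time.time()
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "command": self.command, "seed": self.seed,
            "config": self.config, "config_hash": self.config_digest,
            "inputs": self.inputs, "outputs": self.outputs,
            "started": self.started, "finished": self.finished,
            "package_version": self.version,
        }
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return path
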