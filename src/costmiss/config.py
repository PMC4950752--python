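"""Run configuration loading, validation and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .cohort import GenerationParams
from .imputation import MIConfig
from .missingness import DropoutPatternConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "RunManifest", "file_digest"]


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full simulation run."""

    cohort: GenerationParams = dataclasses.field(default_factory=GenerationParams)
    mi: MIConfig = dataclasses.field(default_factory=MIConfig)
    pattern: DropoutPatternConfig = dataclasses.field(default_factory=DropoutPatternConfig)
    volume: float | None = None
    n_iter: int = 1000
    seed: int = 0

    def validate(self) -> "RunConfig":
        self.cohort.validate()
        self.mi.validate()
        self.pattern.validate()
        if self.volume is not None and not 0 <= self.volume < 1:
            raise ConfigError(f"volume must be in [0, 1), got {self.volume}")
        if self.n_iter < 1:
            raise ConfigError("n_iter must be positive")
        return self


def _build(cls, section: dict, where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")
    coerced = {}
    for f in dataclasses.fields(cls):
        if f.name in section:
            v = section[f.name]
            if isinstance(v, list):
                v = tuple(v)
            if f.name == "correlations" and isinstance(v, dict):
                v = {tuple(k.split("__")): float(val) for k, val in v.items()}
            coerced[f.name] = v
    try:
        obj = cls(**coerced)
        if hasattr(obj, "validate"):
            obj.validate()
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {where} configuration: {exc}") from exc
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    Top-level sections ``cohort``, ``mi`` and ``pattern`` map onto
    GenerationParams, MIConfig and DropoutPatternConfig; top-level scalars
    ``volume``, ``n_iter`` and ``seed`` configure the experiment.  Unknown
    keys are rejected with the offending name; omitted fields take their
    defaults.  Correlation overrides use ``var__var`` keys.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    known_top = {"cohort", "mi", "pattern", "volume", "n_iter", "seed"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    # convenience: a bare {n: ..., seed: ...} config configures the cohort
    cfg = RunConfig(
        cohort=_build(GenerationParams, raw.get("cohort", {}), "cohort"),
        mi=_build(MIConfig, raw.get("mi", {}), "mi"),
        pattern=_build(DropoutPatternConfig, raw.get("pattern", {}), "pattern"),
        volume=raw.get("volume"),
        n_iter=raw.get("n_iter", 1000),
        seed=raw.get("seed", 0),
    )
    return cfg.validate()


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to replay a run: config snapshot, seeds, digests."""

    config: dict
    master_seed: int
    stage_seeds: dict = dataclasses.field(default_factory=dict)
    version: str = "0.1.0"
    started: str = dataclasses.field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    files: dict = dataclasses.field(default_factory=dict)

    def record_file(self, role: str, path: str | Path) -> None:
        self.files[role] = {"path": str(path), "sha256_16": file_digest(path)}

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))
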