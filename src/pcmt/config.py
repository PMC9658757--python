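"""Run configuration: YAML parsing, validation and provenance logging."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .data import ExpressionDataset, load_dataset
from .selection import threshold_grid

__all__ = ["RunConfig", "ConfigError", "parse_threshold_spec"]


class ConfigError(ValueError):
    """A run configuration is invalid; the message names the offending field."""


def parse_threshold_spec(spec: str) -> list[float]:
    """Resolve a ``start:stop:step`` threshold-grid spec."""
    parts = spec.split(":")
    if len(parts) != 3:
        raise ConfigError(f"thresholds: expected start:stop:step, got {spec!r}")
    try:
        start, stop, step = (float(p) for p in parts)
    except ValueError as e:
        raise ConfigError(f"thresholds: non-numeric component in {spec!r}") from e
    return threshold_grid(start, stop, step)


@dataclass
class RunConfig:
    """Validated configuration for an evaluation/robustness/ranking run."""

    matrix: Path
    labels: Path
    annotations: Optional[Path] = None
    scheme: str = "loocv"  # 5fcv | loso | loocv
    models: list[str] = field(default_factory=lambda: ["pcmt", "pooled_lr"])
    thresholds: str = "0.15:0.275:0.025"
    mode: str = "signed"
    n_repeats: int = 8
    seed: int = 0
    out_dir: Path = Path("pcmt_out")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config: top level must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"config: unknown field(s) {sorted(unknown)}")
        for key in ("matrix", "labels", "annotations", "out_dir"):
            if key in raw and raw[key] is not None:
                raw[key] = Path(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("matrix", "labels"):
            p = getattr(self, key)
            if p is None or not Path(p).exists():
                raise ConfigError(f"{key}: path does not exist: {p}")
        if self.annotations is not None and not Path(self.annotations).exists():
            raise ConfigError(f"annotations: path does not exist: {self.annotations}")
        if self.scheme not in ("5fcv", "loso", "loocv"):
            raise ConfigError(f"scheme: must be 5fcv, loso or loocv, got {self.scheme!r}")
        if self.mode not in ("signed", "positive_only"):
            raise ConfigError(f"mode: must be signed or positive_only, got {self.mode!r}")
        parse_threshold_spec(self.thresholds)

    def resolved(self) -> dict:
        d = {k: str(v) if isinstance(v, Path) else v
             for k, v in self.__dict__.items()}
        d["threshold_values"] = parse_threshold_spec(self.thresholds)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.resolved(), sort_keys=True).encode()
        ).hexdigest()[:16]

    def load(self) -> ExpressionDataset:
        return load_dataset(self.matrix, self.labels, self.annotations)
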