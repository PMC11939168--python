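"""YAML run configuration: parsing, validation, and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .counter import CounterConfig
from .errors import ConfigError
from .simulator import NoiseConfig, SimulationConfig


def _build(cls, section: dict[str, Any], where: str):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"{where}: unknown field(s) {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in section.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{where}: {exc}")


@dataclass
class RunConfig:
    """Composite configuration for the CLI pipeline."""

    counter: CounterConfig = field(default_factory=CounterConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    noise: NoiseConfig | None = None
    dialect: str = "jsonl"
    image_size: tuple[int, int] | None = None
    fps: float | None = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "RunConfig":
        doc = dict(doc or {})
        kwargs: dict[str, Any] = {}
        if "counter" in doc:
            kwargs["counter"] = _build(CounterConfig, doc.pop("counter"), "counter")
        if "simulation" in doc:
            kwargs["simulation"] = _build(
                SimulationConfig, doc.pop("simulation"), "simulation"
            )
        if "noise" in doc:
            section = doc.pop("noise")
            kwargs["noise"] = (
                None if section is None else _build(NoiseConfig, section, "noise")
            )
        for key in ("dialect", "log_level"):
            if key in doc:
                kwargs[key] = doc.pop(key)
        if "image_size" in doc:
            size = doc.pop("image_size")
            kwargs["image_size"] = None if size is None else tuple(size)
        if "fps" in doc:
            kwargs["fps"] = doc.pop("fps")
        if doc:
            raise ConfigError(f"unknown top-level field(s) {sorted(doc)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file does not exist: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if doc is not None and not isinstance(doc, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(doc or {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "counter": asdict(self.counter),
            "simulation": asdict(self.simulation),
            "noise": None if self.noise is None else asdict(self.noise),
            "dialect": self.dialect,
            "image_size": self.image_size,
            "fps": self.fps,
            "log_level": self.log_level,
        }

    def hash(self) -> str:
        """Short stable digest of the full configuration, for provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
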