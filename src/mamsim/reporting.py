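"""Configuration, serialization and logging for the study pipeline.

A run is fully described by a :class:`RunConfig`; every output directory
receives a JSON manifest echoing that configuration (plus the package
version), so any result file can be regenerated from its manifest alone.
CSV output uses the RFC-4180 dialect with UTF-8 encoding and "." decimals,
with a stable column order, so identical configurations produce
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__

__all__ = ["RunConfig", "load_config_file", "write_csv", "write_manifest", "setup_logging"]

logger = logging.getLogger("mamsim")

_COMMANDS = ("design", "simulate", "replicate", "misestimate", "cost")


@dataclass
class RunConfig:
    """Serializable description of one command-line run."""

    command: str = "design"
    p0: float = 0.30
    delta: float = 0.30
    arms: int = 4
    stages: int = 3
    alpha: float = 0.05
    power: float = 0.90
    reps: int = 10_000
    seed: int = 12_345
    quadrature: int = 20
    unit_cost: float = 1000.0
    stage_cost: float = 0.0
    hypothesis: str = "lfc"
    out: str | None = None
    verbosity: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.command not in _COMMANDS:
            raise ValueError(f"unknown command {self.command!r}; expected one of {_COMMANDS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def load_config_file(path) -> dict:
    """Read a YAML or JSON configuration file into a flat dict."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must contain a mapping")
    return data


def merge_config(defaults: "RunConfig", file_values: dict, cli_values: dict) -> "RunConfig":
    """Apply precedence: CLI flags override file values override defaults."""
    merged = defaults.to_dict()
    for source, values in (("config file", file_values), ("command line", cli_values)):
        for key, value in values.items():
            if value is None:
                continue
            if key not in merged:
                raise ValueError(f"unknown configuration key {key!r} from {source}")
            merged[key] = value
    config = RunConfig.from_dict(merged)
    logger.debug("effective configuration: %s", config.to_dict())
    return config


def write_csv(frame: pd.DataFrame, path, columns=None) -> Path:
    """Write a DataFrame as UTF-8 RFC-4180 CSV with a stable column order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if columns is not None:
        frame = frame.loc[:, list(columns)]
    frame.to_csv(path, index=False, lineterminator="\r\n", encoding="utf-8")
    logger.info("wrote %d rows to %s", len(frame), path)
    return path


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(config: RunConfig, path, extra: dict | None = None) -> Path:
    """JSON manifest with the full configuration, seed and package version."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "package": "mamsim",
        "version": __version__,
        "config": config.to_dict(),
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def setup_logging(verbosity: int = 0) -> None:
    """Timestamped log lines; -v for info, -vv for debug."""
    level = logging.WARNING - 10 * min(int(verbosity), 2)
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        datefmt="%Y-%m-%dT%H:%M:%S",
        force=True,
    )
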