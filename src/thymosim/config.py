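"""Structured run configuration (YAML) with strict key validation."""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields as dc_fields, asdict
from pathlib import Path
from typing import Any

import yaml

from .params import ModelParams, InvalidParameterError
from .scenarios import EXPERIMENT_NAMES


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass
class RunConfig:
    """One fully specified, reproducible simulation run."""

    experiment: str = "wt"
    ndim: int = 2
    n: int = 256
    L: float = 3000.0
    rng_seed: int = 0
    t_max: float = 2000.0
    dt_max: float = 0.1
    n_snapshots: int = 8
    output_dir: str = "runs"
    overrides: dict[str, Any] = field(default_factory=dict)
    extra: dict[str, Any] = field(default_factory=dict)

    def params(self) -> ModelParams:
        from .scenarios import SEEDED_EXPERIMENTS
        base = SEEDED_EXPERIMENTS.get(self.experiment, {})
        return ModelParams().with_overrides(**{**base, **self.overrides})

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_PARAM_KEYS = {f.name for f in dc_fields(ModelParams)}
_TOP_KEYS = {f.name for f in dc_fields(RunConfig)}


def _nearest(key: str, candidates: set[str]) -> str:
    close = difflib.get_close_matches(key, sorted(candidates), n=1)
    return f" (did you mean {close[0]!r}?)" if close else ""


def parse_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Accepts a path, YAML text, or an already-parsed mapping.  Unknown
    top-level keys and unknown parameter overrides are rejected with the
    nearest valid key named; defaults fill everything unset.
    """
    if isinstance(source, dict):
        data = dict(source)
    else:
        text = Path(source).read_text() if (
            isinstance(source, Path) or
            (isinstance(source, str) and "\n" not in source and Path(source).is_file())
        ) else str(source)
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError("configuration must be a mapping")

    unknown = set(data) - _TOP_KEYS
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown configuration key {key!r}"
                          f"{_nearest(key, _TOP_KEYS | _PARAM_KEYS)}")

    overrides = data.get("overrides") or {}
    if not isinstance(overrides, dict):
        raise ConfigError("'overrides' must be a mapping of parameter -> value")
    bad = set(overrides) - _PARAM_KEYS
    if bad:
        key = sorted(bad)[0]
        raise ConfigError(f"unknown parameter override {key!r}"
                          f"{_nearest(key, _PARAM_KEYS)}")

    cfg = RunConfig(**{**data, "overrides": dict(overrides)})
    if cfg.experiment not in EXPERIMENT_NAMES:
        raise ConfigError(f"unknown experiment {cfg.experiment!r}; "
                          f"valid: {sorted(EXPERIMENT_NAMES)}")
    if cfg.ndim not in (2, 3):
        raise ConfigError("ndim must be 2 or 3")
    for key in ("n", "t_max", "dt_max", "L"):
        val = getattr(cfg, key)
        if not isinstance(val, (int, float)) or val <= 0:
            raise ConfigError(f"{key!r} must be a positive number, got {val!r}")
    try:
        cfg.params()
    except InvalidParameterError as err:
        raise ConfigError(str(err)) from err
    return cfg


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config back to YAML (lossless round trip)."""
    return yaml.safe_dump(cfg.to_dict(), sort_keys=True)
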