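"""Shared YAML/JSON run configuration for the command-line pipeline."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .growth_model import ModelParameters
from .labeling_model import LabelSchedule
from .synthetic_data import StudyDesign


class ConfigError(ValueError):
    """A run configuration is missing a key or holds an invalid value."""


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) configuration file."""
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ConfigError(f"config file {path} must contain a mapping at top level")
    return dict(config)


def require(config: Mapping[str, Any], key: str, context: str = "config") -> Any:
    if key not in config:
        raise ConfigError(f"missing required key {key!r} in {context}")
    return config[key]


def _build(cls, block: Mapping[str, Any], context: str):
    known = {f.name for f in fields(cls)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {context}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {context}: {exc}") from exc


def params_from_config(config: Mapping[str, Any]) -> ModelParameters:
    """Model parameters from the ``params`` block (defaults where omitted)."""
    return _build(ModelParameters, dict(config.get("params", {})), "params block")


def schedule_from_config(config: Mapping[str, Any]) -> LabelSchedule:
    return _build(LabelSchedule, dict(config.get("schedule", {})), "schedule block")


def design_from_config(config: Mapping[str, Any]) -> StudyDesign:
    block = dict(config.get("design", {}))
    for key in ("weeks", "colonies_per_week"):
        if key in block:
            block[key] = tuple(block[key])
    return _build(StudyDesign, block, "design block")
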