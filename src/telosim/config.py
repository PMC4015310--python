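"""Flat key-value configuration files (YAML / JSON) for ModelParams.

Every field of :class:`~telosim.params.ModelParams` maps to one top-level
key; an empty file yields all defaults.  Unknown keys are rejected by name
rather than ignored, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Union

import yaml

from .params import ModelParams

__all__ = ["params_to_dict", "params_from_dict", "load_config", "save_config"]

_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def params_to_dict(params: ModelParams) -> dict:
    """Flat, JSON/YAML-serialisable view of the parameters."""
    out = dataclasses.asdict(params)
    for key in ("bimodal_means", "bimodal_sds"):
        if out[key] is not None:
            out[key] = list(out[key])
    return out


def params_from_dict(data: dict) -> ModelParams:
    """Build validated ModelParams from a flat mapping (defaults applied)."""
    if not isinstance(data, dict):
        raise ValueError(f"config must be a mapping, got {type(data).__name__}")
    unknown = sorted(set(data) - _FIELDS)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    data = dict(data)
    for key in ("bimodal_means", "bimodal_sds"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    try:
        return ModelParams(**data)
    except TypeError as exc:
        raise ValueError(f"bad config value: {exc}") from exc


def load_config(path: Union[str, Path]) -> ModelParams:
    """Load and validate a YAML or JSON parameter file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    return params_from_dict(data)


def save_config(params: ModelParams, path: Union[str, Path]) -> None:
    """Write parameters to YAML (or JSON if the suffix says so)."""
    path = Path(path)
    data = params_to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
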