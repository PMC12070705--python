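"""Configuration loading.

All tunables ship in ``defaults.yaml`` inside the package; a user file with
the same structure overrides any subset of keys (deep merge).
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional

import yaml


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def default_config() -> dict:
    """The packaged defaults as a plain nested dict."""
    text = resources.files("ppgbp").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path: Optional[str | Path] = None,
                overrides: Optional[Mapping[str, Any]] = None) -> dict:
    """Load defaults, optionally merged with a user YAML file and/or an
    in-memory override mapping (applied in that order)."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg
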