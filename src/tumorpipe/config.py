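"""Pipeline configuration: nested defaults, YAML/JSON loading, strict keys.

Unknown keys are rejected rather than ignored so a typo in a config file
cannot silently fall back to a default.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["DEFAULT_CONFIG", "default_config", "load_config", "merge_config"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "verbosity": 1,
    "preprocess": {
        "grid_rows": 8,
        "grid_cols": 8,
        "clip_norm": 0.03,
        "n_levels": 256,
    },
    "segment": {
        "polarity": "above",
        "min_area": 25,
        "opening": False,
        "max_region_fraction": 0.1,
        "source": "original",
    },
    "lnq": {
        "learning_rate": 0.1,
        "epochs": 50,
        "clusters_per_class": 3,
        "beta": None,
    },
    "synthetic": {
        "shape": [128, 128],
        "contrast_window": [100, 140],
        "bias_amplitude": 10.0,
        "noise_sigma": 5.0,
        "tumor_delta": 80.0,
        "tumor_fraction": 0.5,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def merge_config(base: dict, override: dict, _path: str = "") -> dict:
    """Deep-merge ``override`` into a copy of ``base``; unknown keys raise."""
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        where = f"{_path}.{key}" if _path else str(key)
        if key not in base:
            raise ConfigurationError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigurationError(f"config section {where} must be a mapping")
            out[key] = merge_config(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Resolve the full config: defaults overlaid with a YAML or JSON file."""
    if path is None:
        return default_config()
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        override = json.loads(text)
    else:
        override = yaml.safe_load(text)
    if override is None:
        override = {}
    if not isinstance(override, dict):
        raise ConfigurationError(f"{path}: config root must be a mapping")
    return merge_config(DEFAULT_CONFIG, override)
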