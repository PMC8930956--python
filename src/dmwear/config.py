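"""Default configuration loading and merging."""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["load_default_config", "load_config", "merge_config"]


def load_default_config() -> dict:
    """The packaged default study configuration as a nested dict."""
    with resources.files("dmwear.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


def merge_config(base: dict, override: dict) -> dict:
    """Recursively merge ``override`` into a deep copy of ``base``."""
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a user YAML file."""
    cfg = load_default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = merge_config(cfg, user)
    return cfg
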