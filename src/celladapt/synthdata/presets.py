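"""Named preset registry backed by a YAML file shipped with the package."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .params import (
    BiopsyPreset,
    ExpressionPreset,
    FateModelParams,
    GrowthPreset,
    PlatePreset,
    ScreenPreset,
)

_KIND_TYPES = {
    "fate": FateModelParams,
    "plate": PlatePreset,
    "expression": ExpressionPreset,
    "screen": ScreenPreset,
    "biopsy": BiopsyPreset,
    "growth": GrowthPreset,
}


@lru_cache(maxsize=None)
def _builtin_presets() -> dict:
    text = resources.files("celladapt.synthdata").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def load_presets(path: Optional[Union[str, Path]] = None) -> dict:
    """Raw preset mapping, from a user YAML file or the built-in registry."""
    if path is None:
        return _builtin_presets()
    with open(path) as fh:
        return yaml.safe_load(fh)


def get_preset(kind: str, name: str, path: Optional[Union[str, Path]] = None):
    """Return a validated preset object, e.g. ``get_preset("fate", "colo858_vem")``."""
    if kind not in _KIND_TYPES:
        raise KeyError(f"unknown preset kind {kind!r}; valid: {sorted(_KIND_TYPES)}")
    registry = load_presets(path)
    section = registry.get(kind, {})
    if name not in section:
        raise KeyError(f"no {kind} preset named {name!r}; valid: {sorted(section)}")
    return _KIND_TYPES[kind].from_dict(section[name])


def preset_names(kind: str) -> list[str]:
    return sorted(load_presets().get(kind, {}))
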