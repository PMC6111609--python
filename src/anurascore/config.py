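"""YAML binding for the configuration dataclasses."""

from __future__ import annotations

from pathlib import Path

import yaml

from .score_series import LFCCConfig
from .mfcc import MFCCConfig
from .synth import CallTemplate, SynthConfig

__all__ = ["load_synth_config", "load_mfcc_config", "load_lfcc_config"]


def _load(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_synth_config(path: str | Path, **overrides) -> SynthConfig:
    data = _load(path) | overrides
    if "class_templates" in data:
        data["class_templates"] = {
            int(cid): CallTemplate(**tpl)
            for cid, tpl in data["class_templates"].items()
        }
    if "class_proportions" in data:
        data["class_proportions"] = tuple(data["class_proportions"])
    return SynthConfig(**data)


def load_mfcc_config(path: str | Path, **overrides) -> MFCCConfig:
    return MFCCConfig(**(_load(path) | overrides))


def load_lfcc_config(path: str | Path, **overrides) -> LFCCConfig:
    return LFCCConfig(**(_load(path) | overrides))
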