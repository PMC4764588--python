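"""YAML serialization of task, network, and learner configurations.

One file can hold any subset of the blocks ``task:``, ``network:``,
``bayes:``, and ``opal:``; each block maps field names of the
corresponding dataclass to values, so a config written by
:func:`save_config` round-trips exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .bayes import DecayParams
from .network import NetworkParams, TanMode
from .opal import OpalParams
from .task import TaskConfig

__all__ = ["load_config", "save_config"]

_BLOCKS = {
    "task": TaskConfig,
    "network": NetworkParams,
    "bayes": DecayParams,
    "opal": OpalParams,
    "tan_mode": TanMode,
}


def _to_dict(obj: Any) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


def save_config(path: str | Path, **blocks: Any) -> None:
    """Write dataclass blocks (task=..., network=..., ...) to YAML."""
    out = {}
    for name, obj in blocks.items():
        if name not in _BLOCKS:
            raise KeyError(f"unknown config block {name!r}")
        out[name] = _to_dict(obj)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config back into dataclass instances keyed by block."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, Any] = {}
    for name, payload in raw.items():
        if name not in _BLOCKS:
            raise KeyError(f"unknown config block {name!r}")
        out[name] = _BLOCKS[name](**payload)
    return out
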