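"""Checkpoint persistence: flat named-parameter archive + JSON sidecar."""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np

from .nn import Module

__all__ = ["save_checkpoint", "load_checkpoint"]


def save_checkpoint(module: Module, path: str | Path, config=None) -> None:
    """Write parameters as an ``.npz`` archive with a ``.json`` config sidecar."""
    path = Path(path)
    np.savez(path, **module.state_dict())
    if config is not None:
        cfg = asdict(config) if is_dataclass(config) else dict(config)
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2, default=str))


def load_checkpoint(module: Module, path: str | Path) -> Module:
    """Load a parameter archive into an already constructed module."""
    with np.load(Path(path)) as archive:
        module.load_state_dict({k: archive[k] for k in archive.files})
    return module


def load_checkpoint_config(path: str | Path) -> dict:
    sidecar = Path(path).with_suffix(".json")
    return json.loads(sidecar.read_text())
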