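"""Declarative run configuration and deterministic seed fan-out.

A run is described by a nested YAML file with sections ``synth``,
``preprocess``, ``model``, ``train``, and ``metrics`` plus a global
``seed``. Unknown top-level keys are rejected. Every artifact a run writes
embeds the configuration hash and the seed so outputs are auditable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "stage_seed", "config_hash"]

_KNOWN_SECTIONS = {"seed", "synth", "preprocess", "model", "train", "metrics",
                   "augment"}


class RunConfig:
    """Validated nested configuration with a stable content hash."""

    def __init__(self, raw: dict):
        unknown = set(raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        self.raw = raw
        self.seed = int(raw.get("seed", 0))

    def section(self, name: str) -> dict:
        return dict(self.raw.get(name, {}))

    @property
    def hash(self) -> str:
        return config_hash(self.raw)

    def provenance(self) -> dict:
        """Stamp embedded in every artifact this run writes."""
        return {"config_hash": self.hash, "seed": self.seed}


def config_hash(raw: dict) -> str:
    blob = json.dumps(raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    return RunConfig(raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (below 2^31)."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)
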