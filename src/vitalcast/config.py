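"""YAML configuration loading, seed fan-out, and run provenance.

Every pipeline stage takes a dataclass config; this module maps YAML files
onto those dataclasses with field-level validation and rejects unknown
keys (suggesting the closest valid name).  A single global seed fans out
to per-stage seeds through a CRC-based derivation so each stage is
independently reproducible, and every artifact directory receives one
``manifest.json`` recording command, config hash, seeds and paths.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import zlib
from dataclasses import dataclass, fields, is_dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Type

import yaml

from .exceptions import ConfigurationError
from .model import ModelConfig
from .prep import RoleSchema
from .synthetic import SimulationParams
from .training import TrainingConfig

__all__ = ["load_config", "derive_seed", "RunManifest", "PACKAGE_VERSION"]

PACKAGE_VERSION = "0.1.0"

_CONFIG_KINDS: dict[str, Type] = {
    "simulation": SimulationParams,
    "schema": RoleSchema,
    "model": ModelConfig,
    "training": TrainingConfig,
}


def derive_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32 of the stage name mixed with seed.

    Kept below 2**31 so it is safe for any RNG or serialisation format.
    """
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def _coerce(cls: Type, raw: dict) -> Any:
    valid = {f.name for f in fields(cls)}
    unknown = set(raw) - valid
    if unknown:
        key = sorted(unknown)[0]
        hint = difflib.get_close_matches(key, valid, n=1)
        if not hint:  # abbreviations like 'lr' match word initials
            hint = [v for v in sorted(valid) if "".join(w[0] for w in v.split("_")) == key]
        if not hint:  # otherwise any subsequence, shortest first
            def is_subseq(s, t):
                it = iter(t)
                return all(ch in it for ch in s)

            hint = sorted((v for v in valid if is_subseq(key, v)), key=len)[:1]
        suffix = f"; did you mean '{hint[0]}'?" if hint else ""
        raise ConfigurationError(f"unknown config key '{key}' for {cls.__name__}{suffix}")
    for f in fields(cls):
        if f.name in raw and isinstance(raw[f.name], list):
            raw[f.name] = tuple(raw[f.name])
    try:
        obj = cls(**raw)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc
    if hasattr(obj, "validate"):
        obj.validate()
    return obj


def load_config(path: str | Path, kind: str):
    """Load and validate one YAML config file.

    ``kind`` is one of 'simulation', 'schema', 'model', 'training'.  An
    empty file yields the kind's defaults where the dataclass defines them.
    """
    if kind not in _CONFIG_KINDS:
        raise ConfigurationError(
            f"unknown config kind '{kind}'; expected one of {sorted(_CONFIG_KINDS)}"
        )
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file not found: {p}")
    raw = yaml.safe_load(p.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {p} must contain a mapping")
    return _coerce(_CONFIG_KINDS[kind], raw)


def config_hash(obj: Any) -> str:
    """Stable short hash of a config dataclass (or plain dict)."""
    if is_dataclass(obj) and not isinstance(obj, type):
        payload = {f.name: _jsonable(getattr(obj, f.name)) for f in fields(obj)}
    else:
        payload = _jsonable(obj)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    return v


@dataclass
class RunManifest:
    """Provenance for one pipeline stage's output directory."""

    command: str
    config_hash: str
    seed: int
    effective_seed: int
    input_paths: list
    output_path: str
    package_version: str = PACKAGE_VERSION
    timestamp: str = ""

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        path = out / "manifest.json"
        path.write_text(
            json.dumps(
                {
                    "command": self.command,
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "effective_seed": self.effective_seed,
                    "input_paths": [str(p) for p in self.input_paths],
                    "output_path": str(self.output_path),
                    "package_version": self.package_version,
                    "timestamp": self.timestamp,
                },
                indent=2,
            )
        )
        return path
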