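"""Run configuration: schema validation, loading, and reproducibility hashes.

A run configuration is a YAML or JSON mapping with a block per concern
(``parameters``, ``renewal``, ``allometry``) plus one block per protocol
(``simulate``, ``sweep``, ``starve``, ``calibrate``, ``synth``).  Unknown
keys anywhere are rejected before any computation starts, and every output
carries the SHA-256 hash of the canonical configuration so reruns are
attributable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

from .allometry import REFERENCE_ALLOMETRY, AllometryConfig
from .parameters import ModelParameters
from .renewal import DEFAULT_RENEWAL, HouseRenewalTable

__all__ = ["ConfigError", "load_config", "validate_config", "config_hash", "RunConfig"]


class ConfigError(ValueError):
    """Raised for a structurally invalid run configuration."""


_SCHEMA = {
    "parameters": {"f", "kf", "b", "t10", "i", "ki", "a", "ka", "fpp", "nbfp"},
    "renewal": {"anchors", "margin_C"},
    "allometry": {"trunk_to_total", "total_to_weight", "trunk_range_um"},
    "seed": None,
    "output_dir": None,
    "log_level": None,
    "simulate": {"temperature_C", "food", "body_weight", "n_house_cycles",
                 "duration_days", "interruption_time_h", "record_stride",
                 "renewals_enabled"},
    "sweep": {"temperature_C", "body_weight", "fc_grid", "n_house_cycles"},
    "starve": {"temperature_C", "body_weight", "fc0", "fc_grid", "n_points",
               "gut0"},
    "calibrate": {"observations", "bounds", "sann_maxiter", "ci_samples",
                  "n_house_cycles"},
    "synth": {"theta", "design", "noise_sd", "relative", "n_house_cycles"},
}


def validate_config(cfg: dict) -> dict:
    """Reject unknown keys at the top level and inside every known block."""
    if not isinstance(cfg, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    for block, allowed in _SCHEMA.items():
        if allowed is None or block not in cfg:
            continue
        section = cfg[block]
        if not isinstance(section, dict):
            raise ConfigError(f"block {block!r} must be a mapping")
        extra = set(section) - allowed
        if extra:
            raise ConfigError(f"unknown keys in block {block!r}: {sorted(extra)}")
    return cfg


def load_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    return validate_config(cfg or {})


def config_hash(cfg: dict) -> str:
    """SHA-256 of the canonical JSON serialisation of the configuration."""
    canonical = json.dumps(cfg, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


class RunConfig:
    """Resolved configuration: typed parameter/renewal/allometry objects plus
    the raw protocol blocks."""

    def __init__(self, cfg: dict):
        self.raw = validate_config(cfg)
        self.hash = config_hash(self.raw)
        self.seed = int(cfg.get("seed", 0))
        self.output_dir = Path(cfg.get("output_dir", "."))
        self.log_level = str(cfg.get("log_level", "INFO"))
        self.parameters = (ModelParameters.from_dict(cfg["parameters"])
                           if "parameters" in cfg else ModelParameters())
        self.renewal = (HouseRenewalTable.from_config(cfg["renewal"])
                        if "renewal" in cfg else DEFAULT_RENEWAL)
        self.allometry = (AllometryConfig.from_dict(cfg["allometry"])
                          if "allometry" in cfg else REFERENCE_ALLOMETRY)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls(load_config(path))

    def block(self, name: str) -> dict:
        if name not in self.raw:
            raise ConfigError(f"configuration is missing the {name!r} block")
        return self.raw[name]
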