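"""Structured YAML configuration for the command-line workflow.

One file holds everything a run needs: column-name mapping for input CSVs,
the verification options, and the simulation block. Missing keys fall back
to defaults, so an empty file (or none at all) is valid.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from .data_model import ConfigurationError
from .synthetic import FEMALE_DEFAULTS, MALE_DEFAULTS, PopulationConfig, SexConfig
from .verification import VerificationOptions

__all__ = ["DEFAULT_CONFIG", "load_config", "population_from_config", "options_from_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "columns": {},  # canonical name -> name in the file
    "seed": None,
    "verification": {
        "common_slope": True,
        "alpha": 0.05,
        "size_bias_window_cm": 25.0,
        "size_bias_bcis": {},
        "x0": {},
    },
    "simulation": {
        "female": {},  # overrides of SexConfig fields; None disables the sex
        "male": {},
        "resid_cross_corr": 0.75,
    },
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a YAML config, merged over :data:`DEFAULT_CONFIG`."""
    if path is None:
        return _deep_merge(DEFAULT_CONFIG, {})
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return _deep_merge(DEFAULT_CONFIG, raw)


def _sex_config(defaults: SexConfig, overrides: dict | None) -> SexConfig | None:
    if overrides is None:
        return None
    from dataclasses import replace

    return replace(defaults, **overrides)


def population_from_config(cfg: dict[str, Any], seed: int | None = None) -> PopulationConfig:
    """Build a :class:`PopulationConfig` from the ``simulation`` block."""
    sim = cfg.get("simulation", {})
    return PopulationConfig(
        female=_sex_config(FEMALE_DEFAULTS, sim.get("female", {})),
        male=_sex_config(MALE_DEFAULTS, sim.get("male", {})),
        resid_cross_corr=sim.get("resid_cross_corr", 0.75),
        seed=seed if seed is not None else cfg.get("seed"),
    )


def options_from_config(cfg: dict[str, Any]) -> VerificationOptions:
    """Build :class:`VerificationOptions` from the ``verification`` block."""
    v = cfg.get("verification", {})
    return VerificationOptions(
        common_slope=bool(v.get("common_slope", True)),
        alpha=float(v.get("alpha", 0.05)),
        size_bias_window_cm=float(v.get("size_bias_window_cm", 25.0)),
        size_bias_bcis=dict(v.get("size_bias_bcis") or {}),
        x0={k: float(val) for k, val in (v.get("x0") or {}).items()},
    )
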