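"""Run configuration: defaults, YAML/JSON loading, validation.

A run config is a plain nested dict; :func:`load_config` deep-merges a user
file over :data:`DEFAULT_CONFIG` and validates the result, reporting the
offending key path on failure.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .optics import ScoreCategory, ScoreThresholds
from .stain import StainMatrix, StainVector
from .synth import CategoryPreset, CohortConfig, default_presets

__all__ = [
    "DEFAULT_CONFIG",
    "ConfigError",
    "load_config",
    "dump_config",
    "thresholds_from_config",
    "stain_matrix_from_config",
    "cohort_from_config",
]


class ConfigError(ValueError):
    """A configuration schema violation, carrying the key path."""

    def __init__(self, key_path: str, message: str):
        self.key_path = key_path
        super().__init__(f"config key '{key_path}': {message}")


DEFAULT_CONFIG: Dict[str, Any] = {
    "seed": 0,
    "optics": {
        "lambda_nm": 600.0,
        "thresholds_um": [0.4, 1.0, 2.0],
        "objectives": [
            {"name": "5x", "magnification": 5, "na": 0.14},
            {"name": "10x", "magnification": 10, "na": 0.30},
            {"name": "20x", "magnification": 20, "na": 0.50},
            {"name": "100x", "magnification": 100, "na": 0.75},
        ],
    },
    "stains": {
        "hematoxylin": [0.650, 0.704, 0.286],
        "dab": [0.269, 0.568, 0.778],
    },
    "cohort": {
        "n_per_category": {"1+": 40, "2+": 40, "3+": 40},
        "image_format": "png",
    },
    "specimen": {
        "n_cells": 10,
        "cell_radius_um": [6.0, 12.0],
        "nucleus_radius_frac": 0.55,
        "nucleus_od": 0.6,
        "psf_sigma_um": 0.10,
        "pixel_scale": 5.11,
        "rgb_noise_sd": 2.0,
        "canvas_um": 110.0,
        "completeness": 1.0,
        "supersample": 4,
    },
    "measure": {
        "k_rois": 4,
        "roi_length_um": 6.0,
        "step_px": 0.25,
        "min_peak_od": 0.05,
        "psf_correction": False,
    },
    "stats": {"bin_width_um": 0.1},
}


# config blocks replaced wholesale by a user override (never merged with
# defaults): a partial stain matrix or cohort plan must be a schema error,
# not silently completed from defaults
_ATOMIC_KEYS = {"stains", "cohort.n_per_category", "optics.objectives"}


def _deep_merge(
    base: Dict[str, Any], override: Dict[str, Any], prefix: str = ""
) -> Dict[str, Any]:
    out = copy.deepcopy(base)
    for key, value in override.items():
        path = f"{prefix}{key}"
        if (
            key in out
            and isinstance(out[key], dict)
            and isinstance(value, dict)
            and path not in _ATOMIC_KEYS
        ):
            out[key] = _deep_merge(out[key], value, prefix=f"{path}.")
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: Optional[Union[str, Path]] = None) -> Dict[str, Any]:
    """Load and validate a run config (YAML or JSON) merged over defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            user = json.loads(text)
        else:
            user = yaml.safe_load(text)
        if user is None:
            user = {}
        if not isinstance(user, dict):
            raise ConfigError("<root>", "config file must contain a mapping")
        cfg = _deep_merge(cfg, user)
    validate_config(cfg)
    return cfg


def dump_config(cfg: Dict[str, Any], path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def validate_config(cfg: Dict[str, Any]) -> None:
    stains = cfg.get("stains")
    if not isinstance(stains, dict):
        raise ConfigError("stains", "missing or not a mapping")
    for name in ("hematoxylin", "dab"):
        vec = stains.get(name)
        if vec is None:
            raise ConfigError(f"stains.{name}", "missing stain vector")
        if len(vec) != 3 or any(v < 0 for v in vec):
            raise ConfigError(f"stains.{name}", "must be 3 non-negative numbers")
    th = cfg.get("optics", {}).get("thresholds_um")
    if th is not None:
        if len(th) != 3:
            raise ConfigError("optics.thresholds_um", "must be a triple")
        try:
            ScoreThresholds(*th)
        except ValueError as exc:
            raise ConfigError("optics.thresholds_um", str(exc)) from None
    npc = cfg.get("cohort", {}).get("n_per_category", {})
    for label, n in npc.items():
        try:
            ScoreCategory.from_label(label)
        except ValueError as exc:
            raise ConfigError("cohort.n_per_category", str(exc)) from None
        if int(n) < 1:
            raise ConfigError("cohort.n_per_category", f"n for {label} must be >= 1")


def thresholds_from_config(cfg: Dict[str, Any]) -> ScoreThresholds:
    return ScoreThresholds(*cfg["optics"]["thresholds_um"])


def stain_matrix_from_config(cfg: Dict[str, Any]) -> StainMatrix:
    stains = cfg["stains"]
    return StainMatrix(
        (
            StainVector("hematoxylin", tuple(stains["hematoxylin"])),
            StainVector("dab", tuple(stains["dab"])),
        )
    )


def cohort_from_config(cfg: Dict[str, Any], master_seed: Optional[int] = None) -> CohortConfig:
    npc = {
        ScoreCategory.from_label(label): int(n)
        for label, n in cfg["cohort"]["n_per_category"].items()
    }
    overrides = {
        k: (tuple(v) if isinstance(v, list) else v)
        for k, v in cfg["specimen"].items()
    }
    return CohortConfig(
        n_per_category=npc,
        master_seed=cfg["seed"] if master_seed is None else master_seed,
        presets=default_presets(),
        specimen_overrides=overrides,
    )
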