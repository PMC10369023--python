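"""Configuration loading and defaults for the pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml

__all__ = ["DEFAULT_CONFIG", "load_config", "config_hash"]

DEFAULT_CONFIG: dict = {
    "observer": {
        "weber_fractions": [0.05, 0.05, 0.05],
        "luminance_weber": 0.05,
        "acuity_cpd": 3.0,
    },
    "acuity": {"k_cycle_to_sigma": 2.0},
    "ranked_filter": {"radius_px": 2, "n_iter": 5, "keep_fraction": 0.5},
    "leia": {"block_px": 2},
    "pipeline": {"distances_cm": [2.0, 5.0, 10.0, 30.0]},
    "cohort": {
        "n_species": 13,
        "class_counts": [3, 4, 6],
        "individuals_per_species": None,
        "fine_pattern_for_defended": True,
        "effect_map": {
            "achromatic_contrast_gain": 3.5,
            "chromatic_contrast_gain": 7.0,
            "element_shrink": 0.5,
            "fine_element_px": 5.0,
            "marking_achromatic_gain": 10.0,
            "marking_chromatic_gain": 4.0,
            "undefended_offset_achromatic": 1.5,
            "undefended_offset_chromatic": 1.0,
        },
        "scene": {
            "image_size_px": [64, 64],
            "pixels_per_cm": 40.0,
            "pixel_noise_sd": 0.10,
        },
    },
    "stats": {"transform": "sqrt", "ddf_method": "satterthwaite", "n_perm": 999},
    "seed": 0,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Merge defaults with an optional YAML/JSON file and CLI overrides."""
    cfg = DEFAULT_CONFIG
    if path is not None:
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        cfg = _deep_merge(cfg, data or {})
    if overrides:
        cfg = _deep_merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config, used as the run id."""
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
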