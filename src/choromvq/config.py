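"""Run configuration: defaults, YAML loading, validation.

Acquisition defaults follow the study protocol (3-angle compounded plane
waves at an effective 1000 Hz over one second, 16.5 MHz center frequency,
c = 1540 m/s). Grid and phantom-arm parameters are the simulator's own
study conditions; the end-to-end demo arms mirror the 21 malignant / 15
benign design.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config", "validate_config"]


def default_config() -> dict:
    return {
        "seed": 0,
        "acquisition": {
            "frame_rate_hz": 1000.0,
            "center_frequency_mhz": 16.5,
            "n_frames": 1000,
            "sound_speed_m_s": 1540.0,
        },
        "grid": {
            "shape": [256, 256],
            "pixel_pitch_um": 50.0,
        },
        "signal": {
            "clutter_to_blood_db": 40.0,
            "snr_db": 20.0,
            "psf_sigma_px": 1.0,
        },
        "recon": {
            "rank_low": 2,
            "rank_high": None,
            "rank_high_frac": 0.9,
            "scales_px": [1.0, 1.5, 2.0, 3.0, 4.0],
            "tophat_radius_px": 8,
        },
        "morpho": {
            "binarize_method": "otsu",
            "binarize_quantile": 0.85,
            "min_object_px": 4,
            "prune_px": 4.0,
            "junction_merge_radius_px": 2.0,
            "murray_exponent": 3.0,
            "local_diameter_k": 5,
            "fd_on_skeleton": True,
            "box_sizes": None,
        },
        "stats": {
            "thickness_cutoff_mm": 2.5,
            "bootstrap_B": 2000,
        },
        "cohort": {
            "n_malignant": 21,
            "n_benign": 15,
            "malignant_arm": {
                "n_bifurcations": [5, 12],        # uniform integer range
                "tortuosity_amplitude_mm": [0.15, 0.35],
                "root_diameter_um": [500, 800],
                "thickness_mean_mm": 3.81,
                "thickness_sd_mm": 2.63,
            },
            "benign_arm": {
                "n_bifurcations": [0, 2],
                "tortuosity_amplitude_mm": [0.0, 0.08],
                "root_diameter_um": [300, 550],
                "thickness_mean_mm": 1.70,
                "thickness_sd_mm": 0.40,
            },
        },
    }


_RANGES = {
    ("acquisition", "frame_rate_hz"): (0.0, None),
    ("acquisition", "center_frequency_mhz"): (0.0, None),
    ("acquisition", "n_frames"): (2, None),
    ("acquisition", "sound_speed_m_s"): (0.0, None),
    ("grid", "pixel_pitch_um"): (0.0, None),
    ("signal", "psf_sigma_px"): (-1e-12, None),
    ("recon", "rank_low"): (-1, None),
    ("morpho", "prune_px"): (-1e-12, None),
    ("stats", "bootstrap_B"): (200, None),
}


def validate_config(cfg: dict) -> dict:
    """Check structure and parameter ranges; raises ValueError with the field path."""
    base = default_config()
    for section, block in cfg.items():
        if section not in base:
            raise ValueError(f"unknown config section {section!r}")
        if isinstance(base[section], dict):
            if not isinstance(block, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            for key in block:
                if key not in base[section]:
                    raise ValueError(f"unknown config key {section}.{key}")
    merged = copy.deepcopy(base)
    for section, block in cfg.items():
        if isinstance(merged[section], dict):
            merged[section].update(block)
        else:
            merged[section] = block
    for (section, key), (lo, hi) in _RANGES.items():
        v = merged[section][key]
        if v is None:
            continue
        if lo is not None and v <= lo:
            raise ValueError(f"{section}.{key} must be > {lo}, got {v}")
        if hi is not None and v >= hi:
            raise ValueError(f"{section}.{key} must be < {hi}, got {v}")
    shape = merged["grid"]["shape"]
    if len(shape) != 2 or any(int(s) < 8 for s in shape):
        raise ValueError("grid.shape must be two dimensions of at least 8 px")
    return merged


def load_config(path: str | Path | None) -> dict:
    """Load a YAML config (or None for defaults) and validate it."""
    if path is None:
        return validate_config({})
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return validate_config(cfg)
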