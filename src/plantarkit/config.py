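"""Central configuration: sampling rate, sensor layout, calibration constants,
zone boundaries, alert thresholds, CNN hyperparameters, and seeds.

Everything tunable lives in :data:`DEFAULT_CONFIG` and can be overridden from a
YAML file (plain key-value text) via :func:`load_config`.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

#: Acquisition rate of the insole stream, Hz.  A 0.6 s analysis window spans
#: 120 samples, which pins the rate to 200 Hz; every module takes the rate from
#: here (or from the series object) rather than hard-coding it.
SAMPLE_RATE_HZ: float = 200.0

#: Samples per gait cycle (and per analysis window).
CYCLE_LENGTH: int = 120

#: Channel names in column order.
CHANNELS: tuple[str, ...] = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8")

DEFAULT_CONFIG: dict[str, Any] = {
    "sample_rate_hz": SAMPLE_RATE_HZ,
    "calibration": {
        # piecewise-linear relative-capacitance response, kPa^-1
        "sensitivity_low": 0.0126,
        "sensitivity_high": 0.0038,
        "breakpoint_kpa": 200.0,
        "detection_limit_kpa": 0.4,
        "max_pressure_kpa": 500.0,
        "baseline_capacitance_pf": 100.0,
    },
    "layout": {
        # normalized insole frame: x 0..1 across the sole, y 0 heel -> 1 toe
        "coordinates": {
            "S1": [0.72, 0.62],
            "S2": [0.60, 0.88],
            "S3": [0.50, 0.66],
            "S4": [0.42, 0.40],
            "S5": [0.35, 0.84],
            "S6": [0.30, 0.62],
            "S7": [0.38, 0.12],
            "S8": [0.60, 0.14],
        },
        # which side of the foot axis the S6/S7 pair sits on
        "left_is_medial": False,
    },
    "pronation": {"threshold": 0.15},
    "zones": {"boundaries_kpa": [50.0, 200.0, 400.0]},
    "activity": {
        "peak_height_kpa": 100.0,
        "refractory_s": 0.3,
        "met": {"STAND": 1.3, "WALK": 3.5, "RUN": 8.0, "JUMP": 10.0},
    },
    "alerts": {
        "spike_threshold_kpa": 500.0,
        "sustained_threshold_kpa": 200.0,
        "sustained_duration_s": 30.0,
        "asymmetry_fraction": 0.45,
        "asymmetry_min_duration_s": 1.0,
        "overuse_duration_s": 1800.0,
        "activity_threshold_kpa": 0.4,
        "fatigue_min_windows": 3,
    },
    "cnn": {
        "filters": [128, 128, 256, 256],
        "kernel_size": 7,
        "pool_stride": 2,
        "epochs": 200,
        "batch_size": 48,
        "learning_rate": 1.0e-3,
        "lr_schedule": "cosine",
        "standardize": True,
    },
    "segmentation": {
        "window": 120,
        "step": 30,
        "majority_fraction": 0.5,
        "circular_pad": True,
    },
    "seed": 2023,
}


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Return the default configuration, optionally overridden from YAML.

    Unknown keys are accepted (forward compatibility); nested dictionaries are
    merged key-wise so a file only needs to state what it changes.
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return _merge(cfg, override)


def save_config(cfg: dict[str, Any], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
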