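"""Run configuration: defaults, YAML/JSON loading, validation.

Defaults reproduce the study's stated settings: 3.8 s analysis windows at
7.5 Hz, Savitzky-Golay order 4 / window 81, skew cutoff 0.6, 30% no-go
trials, 50% laser trials, 1000 permutations with the 2.5/97.5 percentile
criterion.  Unknown keys are rejected on load.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .exceptions import ParameterError

DEFAULTS: dict = {
    "seed": 0,
    "session": {
        "task": "discrimination",
        "stimulus_levels": None,
        "nogo_fraction": 0.30,
        "laser_fractions": {"none": 0.5, "sensory": 0.5},
        "n_trials": 300,
        "max_consecutive_same": 2,
    },
    "observer": {"g": 0.15, "l": 0.10, "u": 2.0, "v": 1.0},
    "observer_by_laser": {},  # e.g. {"sensory": {"g": .., "l": .., "u": .., "v": ..}}
    "calcium": {
        "n_cells": 100,
        "frac_selective": 0.30,
        "amp_by_group": {"G5-hit": 20.0, "G0-CR": 5.0},
        "nonselective_amp": 12.5,
        "amp_sd": 4.0,
        "kernel_rise": 0.2,
        "kernel_decay": 1.5,
        "noise_sd": 1.0,
        "drift_amplitude": 2.0,
        "drift_period": 120.0,
        "baseline_f0": 100.0,
        "sampling_rate": 7.5,
        "baseline_window_s": 3.8,
        "sensory_window_s": 3.8,
        "pre_s": 4.0,
        "post_s": 5.6,
        "laser_amp_scale": {},
    },
    "analysis": {
        "sg_window": 81,
        "sg_order": 4,
        "clip_percentile": 10.0,
        "skew_cutoff": 0.6,
        "alpha": 0.05,
        "min_trials": 5,
        "n_perm": 1000,
        "perm_percentiles": [2.5, 97.5],
        "n_thresholds": 1000,
    },
    "optics": {
        "power_mw": 4.0,
        "core_diameter_um": 200.0,
        "numerical_aperture": 0.5,
        "expression_area_mm2": 1.0,
        "irradiance_loss_fraction": 1.0,
    },
    "pipeline": {
        "save_traces": False,
    },
}

#: keys whose dict values are free-form maps, not validated sub-sections
_OPEN_MAPS = {"laser_fractions", "amp_by_group", "laser_amp_scale",
              "observer_by_laser"}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ParameterError(f"unknown configuration key: {here}")
        if isinstance(defaults[key], dict) and key not in _OPEN_MAPS:
            if not isinstance(val, dict):
                raise ParameterError(f"configuration section {here} must be a mapping")
            out[key] = _merge(defaults[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(source=None) -> dict:
    """Build a validated configuration.

    ``source`` may be None (pure defaults), a dict of overrides, or a path to
    a YAML or JSON file.  Unknown keys raise :class:`ParameterError`.
    """
    if source is None:
        return copy.deepcopy(DEFAULTS)
    if isinstance(source, dict):
        return _merge(DEFAULTS, source)
    path = Path(source)
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ParameterError("configuration file must contain a mapping")
    return _merge(DEFAULTS, data)
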