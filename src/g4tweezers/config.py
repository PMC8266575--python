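"""Configuration: default experiment constants and YAML overrides.

Config files are flat YAML with ``polymer``, ``protocol`` and ``noise``
sections; unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import copy

import yaml

from .bell import RampProtocol
from .polymer import PolymerParams
from .simulate import NoiseModel

__all__ = [
    "DEFAULT_CONFIG",
    "load_config",
    "polymer_from_config",
    "protocol_from_config",
    "noise_from_config",
]

DEFAULT_CONFIG: dict = {
    "polymer": {
        "persistence_length_nm": 0.8,
        "contour_per_nt_nm": 0.56,
        "folded_extent_nm": 2.0,
        "kBT_pN_nm": 4.11,
    },
    "protocol": {
        "f_start": 1.0,
        "f_end": 60.0,
        "loading_rate": 2.0,
        "hold_force": 1.0,
        "hold_time": 30.0,
        "kBT": 4.11,
    },
    "noise": {
        "sigma_step_nm": 0.6,
        "sigma_bead_nm": 1.0,
        "trace_rate_hz": 100.0,
    },
}


def load_config(path=None) -> dict:
    """Defaults, optionally overridden section-by-section from a YAML file."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for section, values in user.items():
        if section not in cfg:
            raise KeyError(f"unknown config section: {section!r}")
        for key, value in (values or {}).items():
            if key not in cfg[section]:
                raise KeyError(f"unknown config key: {section}.{key}")
            cfg[section][key] = value
    return cfg


def polymer_from_config(cfg: dict) -> PolymerParams:
    p = cfg["polymer"]
    return PolymerParams(
        persistence_length=p["persistence_length_nm"],
        contour_per_nt=p["contour_per_nt_nm"],
        kBT=p["kBT_pN_nm"],
        folded_extent=p["folded_extent_nm"],
    )


def protocol_from_config(cfg: dict) -> RampProtocol:
    return RampProtocol(**cfg["protocol"])


def noise_from_config(cfg: dict) -> NoiseModel:
    n = cfg["noise"]
    return NoiseModel(
        sigma_step=n["sigma_step_nm"],
        sigma_bead=n["sigma_bead_nm"],
        trace_rate=n["trace_rate_hz"],
    )
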