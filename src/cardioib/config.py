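"""Structured text configuration.

Runs are configured by YAML documents layered over a named preset
(``desk``, ``desk-mi``, ``healthy``, ``mi-patient``).  The desk presets
are sized for a single CPU; ``healthy``/``mi-patient`` carry the
subject-derived full-resolution conditions (grid 96x96x128 over a
15x15x20 cm box, beta_s = 1.0e6 dyne/cm^2, mu = 0.04 g/(cm s)) and are
intended for cluster runs.

Note on viscosity: the blood viscosity default is 0.04 g/(cm s) = 4 cP.
A literal reading of "0.04 cP" would be two orders of magnitude below
water and inconsistent with cardiac fluid--structure practice, so the
CGS value is taken as authoritative.
"""

from __future__ import annotations

from dataclasses import asdict

import yaml

from cardioib.protocols import (DESK_BETA_S_KPA, DESK_DRAG, DESK_GEOMETRY,
                                DESK_GRID, DESK_KAPPA, PRESETS, desk_protocol)

__all__ = ["default_config", "load_config"]


def default_config(preset: str = "desk") -> dict:
    """Full configuration dictionary for a named preset."""
    if preset in ("desk", "desk-mi"):
        mi = preset == "desk-mi"
        prot = desk_protocol(mi=mi)
        return {
            "preset": preset,
            "mi": mi,
            "geometry": asdict(DESK_GEOMETRY),
            "grid": dict(DESK_GRID),
            "material": {"name": "healthy", "beta_s_kpa": DESK_BETA_S_KPA,
                         "c_a_mi": 7.5 if mi else 1.0},
            "active": {"T_scale": 1.2 if mi else 1.0},
            "numerics": {"kappa_base": DESK_KAPPA, "drag": DESK_DRAG,
                         "quad_density": 0.5},
            "protocol": asdict(prot),
        }
    if preset in PRESETS:
        p = PRESETS[preset]
        return {
            "preset": preset,
            "mi": preset == "mi-patient",
            "geometry": asdict(p["geometry"]),
            "grid": dict(p["grid"]),
            "material": {"name": "healthy", "beta_s_kpa": 100.0,
                         "c_a_mi": p.get("c_a_mi", 1.0)},
            "active": {"T_scale": p["T_scale"]},
            "numerics": {"kappa_base": 1.0e6, "drag": 0.0, "quad_density": 2.0},
            "protocol": asdict(p["protocol"]),
            "targets": {"edv_ml": p["measured_edv_ml"],
                        "esv_ml": p["measured_esv_ml"]},
        }
    raise KeyError(f"unknown preset {preset!r}; "
                   f"choose from desk, desk-mi, healthy, mi-patient")


def _deep_update(base: dict, override: dict) -> dict:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


def load_config(path=None, preset: str = "desk", overrides: dict | None = None) -> dict:
    """Preset defaults, optionally layered with a YAML file and overrides."""
    cfg = default_config(preset)
    if path is not None:
        with open(path) as fh:
            _deep_update(cfg, yaml.safe_load(fh) or {})
    if overrides:
        _deep_update(cfg, overrides)
    return cfg
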