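"""Declarative run configuration: defaults, validation, presets."""

from __future__ import annotations

from pathlib import Path

import yaml

__all__ = ["DEFAULTS", "validate_config", "load_config", "paper_scale_preset"]

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "runs/default",
    "factors": {
        "n_factors": 6,
        "n_speeds": 8,
        "freq_lo": 0.8,
        "freq_hi": 2.1,
        "harmonic_amps": [1.0, 0.4, 0.15],
        "amp_slope": 0.05,
    },
    "population": {
        "n_units": 50,
        "ellipse_radius": 20.0,
        "speed_axis_gap": 4.0,
        "tilt_per_bin": 0.06,
        "output_dim_amp": 3.0,
        "noise_sd": 0.0,
    },
    "rnn": {
        "n_units": 50,
        "protocol": "graded",
        "dt_ms": 4.0,
        "tau_steps": 10.0,
        "total_steps": 2000,
        "max_iterations": 8000,
        "learning_rate": 2e-3,
        "noise_var": 0.0,
    },
    "normalize": {"mode": "soft", "constant": 5.0},
    "align": {"max_scale": 0.15},
    "smooth": {"sd_ms": 20.0},
    "pca": {"n_components": 12},
    "analysis": {
        "tangling_dims": 12,
        "epsilon_coef": 0.1,
        "reference_bin": 5,
        "regression_pcs": [2, 3],
        "control_trials": 20,
    },
}


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if key in user:
            uval = user[key]
            if isinstance(dval, dict):
                if not isinstance(uval, dict):
                    raise ValueError(f"config key {path}{key} must be a mapping")
                out[key] = _merge(dval, uval, f"{path}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = dval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(path + k for k in unknown)}")
    return out


def validate_config(user: dict | None) -> dict:
    """Fill defaults, reject unknown keys, check basic sanity."""
    cfg = _merge(DEFAULTS, user or {})
    if not isinstance(cfg["seed"], int) or cfg["seed"] < 0:
        raise ValueError("seed must be a non-negative integer")
    if cfg["factors"]["freq_lo"] >= cfg["factors"]["freq_hi"]:
        raise ValueError("freq_lo must be below freq_hi")
    if cfg["rnn"]["protocol"] not in ("graded", "one_hot", "feedback"):
        raise ValueError("rnn.protocol must be graded | one_hot | feedback")
    return cfg


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return validate_config({})
    text = Path(path).read_text()
    return validate_config(yaml.safe_load(text) or {})


def paper_scale_preset() -> dict:
    """The constants of the original study conditions."""
    return validate_config(
        {
            "rnn": {"n_units": 50, "dt_ms": 4.0, "tau_steps": 10.0,
                    "total_steps": 2000},
            "factors": {"n_speeds": 8},
            "normalize": {"constant": 5.0},
            "analysis": {"epsilon_coef": 0.1, "tangling_dims": 12},
        }
    )
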