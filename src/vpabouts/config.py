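"""YAML configuration with study defaults."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .errors import ConfigError

DEFAULTS: dict = {
    "cutpoints": {"light_lo": 56.3, "mod_lo": 191.6, "vig_lo": 695.8},
    "nonwear": {
        "angle_threshold_deg": 2.0,
        "min_duration_min": 30,
        "window_start_hour": 8,
        "window_end_hour": 22,
    },
    "sleep": {"fallback_wake": "07:30", "fallback_bed": "23:00"},
    "output": {"decimals": 1},
    "simulate": {
        "n_subjects": 10,
        "frac_boys": 0.5,
        "compliance_prevalence": 0.25,
        "pe_days": 2,
        "pe_vigorous_prob": 0.5,
        "nonwear_daily_prob": 0.15,
        "start_date": "2020-01-13",
        "n_days": 8,
    },
}


def load_config(path=None) -> dict:
    """Merge a user YAML file over the defaults (one level deep)."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is None:
        return cfg
    try:
        user = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(user, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for section, values in user.items():
        if section not in cfg:
            raise ConfigError(f"{path}: unknown config section {section!r}")
        if not isinstance(values, dict):
            raise ConfigError(f"{path}: section {section!r} must be a mapping")
        cfg[section].update(values)
    return cfg
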