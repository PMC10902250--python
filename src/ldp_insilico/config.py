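"""Structured run configuration (YAML) for the command-line interface.

The config file mirrors the library's dataclasses:

.. code-block:: yaml

    trial:
      n_patients: 5000
      replicates: 10
      master_seed: 1
      arms: [psv, pav, psv_ecco2r, pav_ecco2r, awake_ecco2r]
      calibrate: true          # grid-calibrate controller constants first
      calibration_n: 2000
    population:
      g_chemo_median: 1.8      # overridden by calibration when enabled
      b_apnea_mean: 34.0
      overrides:               # optional per-parameter spec overrides
        c_lung: {family: truncnorm, mean: 47, sd: 13, lower: 8, upper: 86}
    constants: {c50: 6.0, atot: 12.0}
    policy: {ps_step: 2.0, max_iter: 20}
"""

from __future__ import annotations

from dataclasses import fields, replace
from typing import Any

import yaml

from .errors import ConfigurationError
from .physiology import ModelConstants
from .population import DistributionSpec, default_population_specs
from .titration import TitrationPolicy

__all__ = ["load_config", "build_runtime"]

_DEFAULT_TRIAL = {
    "n_patients": 5000,
    "replicates": 10,
    "master_seed": 1,
    "arms": ["psv", "pav", "psv_ecco2r", "pav_ecco2r", "awake_ecco2r"],
    "calibrate": True,
    "calibration_n": 2000,
}


def load_config(path: str | None) -> dict[str, Any]:
    """Read a YAML config file merged over the defaults."""
    cfg: dict[str, Any] = {"trial": dict(_DEFAULT_TRIAL), "population": {},
                           "constants": {}, "policy": {}}
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    for key, value in user.items():
        if key not in cfg:
            raise ConfigurationError(f"{path}: unknown config section {key!r}")
        if not isinstance(value, dict):
            raise ConfigurationError(f"{path}: section {key!r} must be a mapping")
        cfg[key].update(value)
    return cfg


def _dataclass_from(cls, block: dict, section: str):
    names = {f.name for f in fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise ConfigurationError(f"{section}: unknown keys {sorted(unknown)}")
    return cls(**block)


def build_runtime(cfg: dict[str, Any]):
    """Turn a merged config dict into (trial kwargs, specs, constants, policy)."""
    trial = dict(_DEFAULT_TRIAL)
    trial.update(cfg.get("trial", {}))

    pop = dict(cfg.get("population", {}))
    overrides = pop.pop("overrides", {}) or {}
    specs = default_population_specs(
        g_chemo_median=float(pop.pop("g_chemo_median", 1.8)),
        b_apnea_mean=float(pop.pop("b_apnea_mean", 34.0)),
    )
    if pop:
        raise ConfigurationError(f"population: unknown keys {sorted(pop)}")
    for name, block in overrides.items():
        if name not in specs:
            raise ConfigurationError(f"population.overrides: unknown parameter {name!r}")
        spec = _dataclass_from(DistributionSpec, dict(block), f"population.overrides.{name}")
        spec.validate(name)
        specs[name] = spec

    constants = _dataclass_from(ModelConstants, dict(cfg.get("constants", {})),
                                "constants")
    constants.validate()
    policy = _dataclass_from(TitrationPolicy, dict(cfg.get("policy", {})),
                             "policy")
    return trial, specs, constants, policy
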