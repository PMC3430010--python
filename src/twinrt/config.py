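"""YAML configuration loading for the command-line interface.

A config file is a flat two-section mapping::

    params:               # TwinParams fields (ms / 1-per-ms units)
      lambda_v: 0.01
      lambda_a: 0.01
      omega: 100
      delta: 20
      mu: 100
      sigma: 10
      soa: 0
    decision:             # DecisionContext fields (optional)
      p_common: 0.5
      t0: -500
      t1: 500
      u11: 1.0
      u10: 0.0
      u21: 0.0
      u20: 1.0
    sweep:                # optional parameter sweep for `predict`
      parameter: omega
      grid: [10, 50, 100, 200]
      outputs: [pr_integration, expected_rt, cre]

CLI flags override file values; every command writes the fully resolved
configuration next to its output as ``<out>.meta.json`` so any table can
be regenerated from its metadata alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .params import TwinConfigError, TwinParams
from .optimal import DecisionContext

SWEEPABLE = set(TwinParams.__dataclass_fields__) | {"p_common"}
KNOWN_OUTPUTS = ("pr_integration", "expected_rt", "cre", "omega_opt", "cre_opt")


class ConfigError(TwinConfigError):
    """Malformed configuration file."""


def load_config(path: str | Path) -> dict:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"params", "decision", "sweep"}
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")
    return raw


def resolve_params(raw: dict, **overrides) -> TwinParams:
    d = dict(raw.get("params") or {})
    d.update({k: v for k, v in overrides.items() if v is not None})
    try:
        return TwinParams.from_dict(d)
    except TypeError as exc:
        raise ConfigError(f"params section: {exc}") from exc


def resolve_decision(raw: dict, **overrides) -> DecisionContext | None:
    d = dict(raw.get("decision") or {})
    d.update({k: v for k, v in overrides.items() if v is not None})
    if not d:
        return None
    try:
        return DecisionContext.from_dict(d)
    except TypeError as exc:
        raise ConfigError(f"decision section: {exc}") from exc


def resolve_sweep(raw: dict) -> dict | None:
    sweep = raw.get("sweep")
    if sweep is None:
        return None
    if not isinstance(sweep, dict) or "parameter" not in sweep or "grid" not in sweep:
        raise ConfigError("sweep section needs 'parameter' and 'grid'")
    name = sweep["parameter"]
    if name not in SWEEPABLE:
        raise ConfigError(f"cannot sweep {name!r}; choose one of {sorted(SWEEPABLE)}")
    grid = [float(g) for g in sweep["grid"]]
    if not grid or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigError("sweep grid must be nonempty and strictly increasing")
    outputs = list(sweep.get("outputs", ["pr_integration", "expected_rt", "cre"]))
    bad = set(outputs) - set(KNOWN_OUTPUTS)
    if bad:
        raise ConfigError(f"unknown sweep outputs {sorted(bad)}")
    return {"parameter": name, "grid": grid, "outputs": outputs}


def write_metadata(out_path: str | Path, payload: dict) -> Path:
    """Echo the fully resolved configuration (plus seeds/versions) beside
    the output file, as ``<out>.meta.json``."""
    meta_path = Path(str(out_path) + ".meta.json")
    meta_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return meta_path
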