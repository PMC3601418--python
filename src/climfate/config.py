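"""Configuration loading, result serialization and run manifests.

The run configuration is a YAML document with the sections below; every
key is optional and falls back to the packaged default, unknown keys are
rejected so typos fail loudly.  Results are written as CSV (10 significant
digits) plus ``summary.json`` and a ``manifest.json`` recording the
configuration hash, package version and seed, so re-running with an
identical configuration and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .bioacc import DEFAULT_CYCLE, BioenergeticParams, ThermalTraits
from .world import DEFAULT_DELTAS, DEFAULT_GEOMETRY, ClimateDelta

_DEFAULT_CONFIG = {
    "world": {
        "n_regions": 4,
        "geometry": dict(DEFAULT_GEOMETRY),
        "region_areas": {},
        "region_temps": {},
    },
    "deltas": [dataclasses.asdict(d) for d in DEFAULT_DELTAS],
    "emissions": {
        "mode": "air_temperate",
        "source_rate": 1000.0,
        "arctic_fraction": 1e-3,
    },
    "chemspace": {
        "logKOA_min": 4.0, "logKOA_max": 14.0,
        "logKAW_min": -6.0, "logKAW_max": 1.0, "step": 0.5,
    },
    "bioacc": {
        "traits": dataclasses.asdict(ThermalTraits()),
        "params": dataclasses.asdict(BioenergeticParams()),
        "cycle": dict(DEFAULT_CYCLE),
        "offsets": [2.0, 3.0],
        "C_wd": 1e-6, "C_diet": None,
    },
    "seed": 0,
}


def default_config() -> dict:
    return json.loads(json.dumps(_DEFAULT_CONFIG))


def _merge(defaults: dict, user: dict, path: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if user is not None and key in user:
            uval = user[key]
            if isinstance(dval, dict):
                if not isinstance(uval, dict):
                    raise ValueError(f"config key {path}{key} must be a mapping")
                out[key] = _merge(dval, uval, f"{path}{key}.")
            else:
                out[key] = uval
        else:
            out[key] = dval
    if user:
        unknown = set(user) - set(defaults)
        if unknown:
            raise ValueError(
                f"unknown config key(s) {sorted(unknown)} under '{path or '/'}'")
    return out


def validate_config(cfg: dict) -> dict:
    """Semantic checks beyond schema shape; returns the config unchanged."""
    for d in cfg["deltas"]:
        ClimateDelta(**d)       # raises on dPrecip <= -1 etc.
    ThermalTraits(**cfg["bioacc"]["traits"])
    BioenergeticParams(**cfg["bioacc"]["params"])
    if cfg["chemspace"]["step"] <= 0:
        raise ValueError("chemspace.step must be positive")
    return cfg


def load_config(path=None) -> dict:
    """Load, merge with defaults and validate a YAML configuration."""
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"{path}: top level must be a mapping")
    # deltas are a list, replaced wholesale when given
    merged = _merge({k: v for k, v in _DEFAULT_CONFIG.items()
                     if k != "deltas"},
                    {k: v for k, v in user.items() if k != "deltas"})
    merged["deltas"] = user.get("deltas", default_config()["deltas"])
    return validate_config(json.loads(json.dumps(merged)))


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    canonical = json.dumps(cfg, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


def deltas_from_config(cfg: dict) -> tuple:
    return tuple(ClimateDelta(**d) for d in cfg["deltas"])


def write_results(results: dict, out_dir, cfg: dict | None = None,
                  seed: int | None = None) -> list[str]:
    """Write result tables and summaries; returns the file inventory.

    ``results`` maps a name either to a DataFrame (written as
    ``<name>.csv``) or to a JSON-serializable object (collected into
    ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inventory = []
    summary = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            fname = f"{name}.csv"
            obj.to_csv(out / fname, index=False, float_format="%.10g")
            inventory.append(fname)
        else:
            summary[name] = obj
    if summary:
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        inventory.append("summary.json")
    manifest = {
        "package": "climfate",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "files": sorted(inventory),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    inventory.append("manifest.json")
    return sorted(inventory)
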