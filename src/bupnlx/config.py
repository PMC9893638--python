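"""YAML configuration: model parameters, trial and simulation settings.

A single human-readable document with a complete default embedding the
published final-model estimates, so every pipeline stage can run without an
external file.  Runs emit a manifest (config hash, seed, package versions)
sufficient to reproduce their outputs exactly; the manifest deliberately
contains no timestamps.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import yaml

from .params import BupParams, NlxParams, OccupancyParams


class ConfigError(KeyError):
    """A missing or malformed configuration key, named by its path."""


@dataclass
class Config:
    bup: BupParams
    nlx: NlxParams
    occupancy: OccupancyParams
    simulation: dict

    def to_dict(self) -> dict:
        return {"bup": asdict(self.bup), "nlx": asdict(self.nlx),
                "occupancy": asdict(self.occupancy),
                "simulation": dict(self.simulation)}

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


DEFAULT_SIMULATION = {
    "n_patients": 1000,    # virtual patients per regimen
    "days": 8,             # dosing days before the steady-state assessment
    "dt": 0.05,            # simulation grid step, h
    "msc_ng_ml": 3.0,      # minimum suppression concentration
    "nlx_threshold_ng_ml": 4.6,
    "nos_mode": "median",
}


def default_config() -> Config:
    return Config(BupParams(), NlxParams(), OccupancyParams(),
                  dict(DEFAULT_SIMULATION))


def load_config(path=None) -> Config:
    """Load a config file; omitted sections/keys fall back to the defaults."""
    if path is None:
        return default_config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    try:
        bup = BupParams(**raw.get("bup", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bup: {exc}") from exc
    try:
        nlx = NlxParams(**raw.get("nlx", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"nlx: {exc}") from exc
    try:
        occ = OccupancyParams(**raw.get("occupancy", {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"occupancy: {exc}") from exc
    sim = dict(DEFAULT_SIMULATION)
    extra = set(raw.get("simulation", {})) - set(DEFAULT_SIMULATION)
    if extra:
        raise ConfigError(f"simulation: unknown keys {sorted(extra)}")
    sim.update(raw.get("simulation", {}))
    return Config(bup, nlx, occ, sim)


def save_config(config: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def manifest(config: Config, seed: int | None, command: str) -> dict:
    import numpy
    import pandas
    import scipy

    from . import __version__
    return {
        "command": command,
        "seed": seed,
        "config_hash": config.hash(),
        "versions": {"bupnlx": __version__, "numpy": numpy.__version__,
                     "scipy": scipy.__version__, "pandas": pandas.__version__},
    }


def write_manifest(config: Config, seed: int | None, command: str, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest(config, seed, command), fh, indent=1, sort_keys=True)
        fh.write("\n")
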