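"""Structured run configuration and constants resolution.

A run config is a YAML mapping.  The ``constants`` block defaults to the
acquisition/analysis constants; the ``kinetics``/``lattice``/``reservoir``
blocks use the canonical key names (k_in, k_on, k_off, k_step, k_out,
c_total_nM, n_sites, site_length_nm, volume_fL, seed).  Every run writes
its resolved configuration next to its outputs so results are reproducible
from the artifact alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import constants as C
from .lattice import LatticeSpec, MotorKinetics, ReservoirSpec

__all__ = ["RunConfig", "load_config", "load_kinetics_config", "ConfigError"]


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


_DEFAULT_CONSTANTS = {
    "pixel_size_nm": C.PIXEL_SIZE_NM,
    "frame_interval_s": C.FRAME_INTERVAL_S,
    "bin_nm": C.BIN_NM,
    "detect_limit_nm": C.DETECT_LIMIT_NM,
    "spindle_max_um": C.SPINDLE_MAX_UM,
    "window_s": C.WINDOW_S,
    "conditioning_nM": C.CONDITIONING_NM,
    "n_draws": C.N_DRAWS_DEFAULT,
}

_KINETICS_KEYS = ("k_in", "k_on", "k_off", "k_step", "k_out", "c_total_nM")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    subcommand: str = ""
    inputs: dict = field(default_factory=dict)
    out_dir: str = "."
    constants: dict = field(default_factory=lambda: dict(_DEFAULT_CONSTANTS))
    seed: int = 0
    options: dict = field(default_factory=dict)

    def resolved(self) -> dict:
        return asdict(self)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.resolved(), fh, indent=2, default=str)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("run config must be a mapping")
    cfg = RunConfig()
    constants = dict(_DEFAULT_CONSTANTS)
    user_constants = raw.get("constants", {})
    if not isinstance(user_constants, dict):
        raise ConfigError("field 'constants' must be a mapping")
    unknown = set(user_constants) - set(_DEFAULT_CONSTANTS)
    if unknown:
        raise ConfigError(f"unknown constants: {sorted(unknown)}")
    constants.update(user_constants)
    cfg.constants = constants
    cfg.seed = int(raw.get("seed", 0))
    cfg.inputs = raw.get("inputs", {})
    cfg.options = raw.get("options", {})
    cfg.out_dir = str(raw.get("out_dir", "."))
    return cfg


def load_kinetics_config(path) -> tuple[MotorKinetics, LatticeSpec, ReservoirSpec, int]:
    """Load a model configuration (kinetics, lattice, reservoir, seed)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    missing = [k for k in _KINETICS_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"missing kinetics keys: {missing}")
    kinetics = MotorKinetics(
        k_in=float(raw["k_in"]),
        k_on=float(raw["k_on"]),
        k_off=float(raw["k_off"]),
        k_step=float(raw["k_step"]),
        k_out=float(raw["k_out"]),
        c_total=float(raw["c_total_nM"]),
    )
    lattice = LatticeSpec(
        n_sites=int(raw.get("n_sites", 125)),
        site_length=float(raw.get("site_length_nm", C.SITE_NM)),
    )
    reservoir = ReservoirSpec(
        volume=float(raw.get("volume_fL", C.CELL_VOLUME_FL)),
        n_filaments=int(raw.get("n_filaments", 1)),
        closed=bool(raw.get("closed", True)),
    )
    return kinetics, lattice, reservoir, int(raw.get("seed", 0))
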