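"""Structured run configuration with schema validation.

A run config is a YAML (or JSON) mapping with a root seed, an output
directory, and per-stage parameter blocks mirroring the parameter
dataclasses.  Unknown keys are rejected with their full key path so typos
surface immediately; every stochastic output records the seed and a
parameter hash.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .params import CellGeometry, ExchangeParams, PhotoParams

__all__ = ["RunConfig", "ConfigError", "load_config", "derive_seed"]


class ConfigError(ValueError):
    pass


_SECTION_TYPES = {"exchange": ExchangeParams, "photo": PhotoParams}

_SCALAR_SECTIONS = {
    "frap": {"n_replisomes", "duration_s", "conc_series_nm"},
    "invivo": {"mechanism", "k_on", "k_off", "n_frames", "n_foci"},
    "cells": {"n_cells", "copies_per_cell", "unit_intensity", "autofluorescence",
              "coverslip_decay_s", "coverslip_amplitude", "n_focus_traces",
              "volume_fl"},
    "kymo": {"n_molecules", "rate_mean_bp_s", "rate_sd_bp_s",
             "processivity_mean_bp", "segment_mean_duration_s", "pixel_size_um",
             "gamma_um_per_kb", "pol1_present"},
    "analysis": {"max_lag_s", "detrend", "smoothing_window_s", "penalty",
                 "min_duration_s", "min_step", "n_components", "relative_sd",
                 "cores_per_complex", "label_efficiency", "pre_frames"},
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "runs"
    log_level: str = "INFO"
    exchange: ExchangeParams = field(default_factory=ExchangeParams)
    photo: PhotoParams = field(default_factory=PhotoParams)
    sections: dict = field(default_factory=dict)

    def section(self, name: str) -> dict:
        return dict(self.sections.get(name, {}))

    def cell_geometry(self) -> CellGeometry:
        vol = self.section("cells").get("volume_fl")
        if vol is None:
            raise ConfigError("missing config key cells.volume_fl "
                              "(cell volume in fL, required for count-cells)")
        return CellGeometry(volume_fl=float(vol))


def _build_dataclass(cls, data: dict, path: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} at {path}")
    coerced = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid values at {path}: {e}") from e


def load_config(path_or_dict) -> RunConfig:
    """Load and validate a run config from YAML/JSON file or dict."""
    if isinstance(path_or_dict, (str, Path)):
        data = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        data = dict(path_or_dict)
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")

    cfg = RunConfig()
    known_top = {"seed", "outdir", "log_level"} | set(_SECTION_TYPES) | set(_SCALAR_SECTIONS)
    unknown = set(data) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    cfg.seed = int(data.get("seed", 0))
    cfg.outdir = str(data.get("outdir", "runs"))
    cfg.log_level = str(data.get("log_level", "INFO"))
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            setattr(cfg, name, _build_dataclass(cls, data[name] or {}, name))
    for name, allowed in _SCALAR_SECTIONS.items():
        block = data.get(name) or {}
        unknown = set(block) - allowed
        if unknown:
            raise ConfigError(f"unknown key(s) {sorted(unknown)} at {name}")
        cfg.sections[name] = dict(block)
    return cfg


def derive_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    ss = np.random.SeedSequence([int(root_seed) & 0x7FFFFFFF,
                                 int.from_bytes(stage.encode()[:8].ljust(8, b"\0"),
                                                "little") & 0x7FFFFFFF])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
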