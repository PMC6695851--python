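"""YAML/JSON run configuration.

Sections: ``physics`` (calibration constants), ``synth`` (cohort and
waveform specs), ``classify`` (grids, folds), ``readout`` (fs, ADC).
Unknown keys are collected and reported as warnings; type errors are
configuration errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .hemodynamics import CalibrationConstants

__all__ = ["RunConfig", "load_config"]

_PHYSICS_KEYS = {
    "eta", "rho", "eps_HbO", "eps_Hb", "kappa", "E", "sigma_p", "h1",
    "poiseuille_pi",
}
_SYNTH_KEYS = {
    "n_subjects", "seed", "dos_positive_prevalence", "bfv_positive_prevalence",
    "control", "d_range", "e_range", "sbp_range", "dbp_range", "spo2_range",
    "hr_range", "dos_range_healthy", "dos_range_diseased", "noise_sd",
    "max_retries", "waveform",
}
_WAVEFORM_KEYS = {
    "duration", "fs", "dc_level", "ac_fraction", "mains_freq", "mains_amp",
    "drift_amp", "drift_period", "noise_sd",
}
_CLASSIFY_KEYS = {"k_grid", "c_exponents", "sigma_exponents", "n_folds"}
_READOUT_KEYS = {"fs", "adc_bits", "vref", "causal"}


@dataclass
class RunConfig:
    physics: CalibrationConstants = field(default_factory=CalibrationConstants)
    synth: dict = field(default_factory=dict)
    waveform: dict = field(default_factory=dict)
    k_grid: tuple[int, ...] = (1, 3, 5, 7, 9, 11, 13, 15)
    c_exponents: tuple[int, ...] = tuple(range(-5, 16, 2))
    sigma_exponents: tuple[int, ...] = tuple(range(-5, 11, 2))
    n_folds: int = 10
    adc_bits: int = 16
    vref: float = 3.3
    causal: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def c_grid(self) -> tuple[float, ...]:
        return tuple(2.0**e for e in self.c_exponents)

    @property
    def sigma_grid(self) -> tuple[float, ...]:
        return tuple(2.0**e for e in self.sigma_exponents)


def _check_keys(section: str, data: dict, allowed: set[str], warns: list[str]) -> dict:
    unknown = set(data) - allowed
    for key in sorted(unknown):
        warns.append(f"unknown key {section}.{key} ignored")
    return {k: v for k, v in data.items() if k in allowed}


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a config file (YAML or JSON); None gives defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    text = path.read_text()
    try:
        data = (
            json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        )
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        return cfg
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")

    top_allowed = {"physics", "synth", "classify", "readout"}
    for key in sorted(set(data) - top_allowed):
        cfg.warnings.append(f"unknown top-level key {key} ignored")

    try:
        physics = _check_keys(
            "physics", data.get("physics", {}) or {}, _PHYSICS_KEYS, cfg.warnings
        )
        cfg.physics = CalibrationConstants(**physics)

        synth = _check_keys(
            "synth", data.get("synth", {}) or {}, _SYNTH_KEYS, cfg.warnings
        )
        cfg.waveform = _check_keys(
            "synth.waveform", synth.pop("waveform", {}) or {},
            _WAVEFORM_KEYS, cfg.warnings,
        )
        for key in ("d_range", "e_range", "sbp_range", "dbp_range", "spo2_range",
                    "hr_range", "dos_range_healthy", "dos_range_diseased"):
            if key in synth:
                synth[key] = tuple(float(v) for v in synth[key])
        cfg.synth = synth

        cls = _check_keys(
            "classify", data.get("classify", {}) or {}, _CLASSIFY_KEYS, cfg.warnings
        )
        if "k_grid" in cls:
            cfg.k_grid = tuple(int(k) for k in cls["k_grid"])
        if "c_exponents" in cls:
            cfg.c_exponents = tuple(int(e) for e in cls["c_exponents"])
        if "sigma_exponents" in cls:
            cfg.sigma_exponents = tuple(int(e) for e in cls["sigma_exponents"])
        if "n_folds" in cls:
            cfg.n_folds = int(cls["n_folds"])

        readout = _check_keys(
            "readout", data.get("readout", {}) or {}, _READOUT_KEYS, cfg.warnings
        )
        if "adc_bits" in readout:
            cfg.adc_bits = int(readout["adc_bits"])
        if "vref" in readout:
            cfg.vref = float(readout["vref"])
        if "causal" in readout:
            cfg.causal = bool(readout["causal"])
        if "fs" in readout:
            cfg.waveform.setdefault("fs", float(readout["fs"]))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration in {path}: {exc}") from exc
    return cfg
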