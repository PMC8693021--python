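"""Readers, writers and configuration for the chamber digital twin.

Oscilloscope recordings arrive as CSV with a time column plus one or two
channels; the current channel is a shunt voltage behind an amplifier, so the
conversion ``I = V_channel / (gain * R_shunt)`` applies, and the chamber
voltage may optionally be corrected for the shunt drop
(``U_chamber = U_in - I R_shunt``).

Configuration is a YAML document with blocks for geometry, circuit, the UQ
study, the well network and monitoring thresholds; unknown keys and bound
violations are rejected with the offending fields named.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

from .circuits import NetworkConfig, circuit_from_dict, default_chamber_circuit
from .geometry import ChamberGeometry
from .spectra import SampledSignal
from .uq import UncertainParameter

__all__ = ["RecordingMeta", "read_recording", "load_config", "Config",
           "default_config_dict"]


@dataclass
class RecordingMeta:
    """How a raw oscilloscope export maps to physical signals."""

    shunt_resistance: float = 1.0  # Ohm
    amplifier_gain: float = 10.0
    voltage_channel: str | None = "CH1"
    current_channel: str | None = "CH2"
    correct_shunt_drop: bool = False

    def __post_init__(self) -> None:
        if self.shunt_resistance <= 0:
            raise ValueError("shunt_resistance must be > 0")
        if self.amplifier_gain <= 0:
            raise ValueError("amplifier_gain must be > 0")


def read_recording(path, meta: RecordingMeta) -> tuple[SampledSignal, SampledSignal]:
    """Read a two-channel oscilloscope CSV into (voltage, current) signals.

    The current channel carries the amplified shunt voltage and is converted
    by ``I = V / (gain * R_shunt)``.  With ``correct_shunt_drop`` the chamber
    voltage is ``U_in - I R_shunt`` (the shunt sits in series, so not the
    entire input voltage drops across the chamber).
    """
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    tcol = next((cols[c] for c in cols if c.lower() in ("time_s", "time", "t")), None)
    if tcol is None:
        raise ValueError(f"{path}: missing time column ('time_s')")
    t = df[tcol].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=0):
        raise ValueError(f"{path}: sampling is not uniform")
    channels = [c for c in df.columns if c != tcol]

    def pick(name):
        if name in cols:
            return df[cols[name]].to_numpy(dtype=float)
        raise ValueError(
            f"{path}: channel {name!r} not found (have {channels})"
        )

    v_raw = pick(meta.voltage_channel) if meta.voltage_channel else None
    i_raw = pick(meta.current_channel) if meta.current_channel else None
    if i_raw is None:
        raise ValueError(f"{path}: a current channel is required")
    current = i_raw / (meta.amplifier_gain * meta.shunt_resistance)
    if v_raw is None:
        raise ValueError(f"{path}: a voltage channel is required")
    voltage = v_raw - current * meta.shunt_resistance if meta.correct_shunt_drop else v_raw
    return (
        SampledSignal(t[0], float(dt[0]), voltage, "voltage"),
        SampledSignal(t[0], float(dt[0]), current, "current"),
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class Config:
    """Validated run configuration."""

    geometry: ChamberGeometry
    circuit: object
    network: NetworkConfig
    uq_parameters: list
    uq_order: int
    truncation_ratio: float
    linearity_limit: float  # V
    alpha_conductivity: float  # 1/degC
    conductivity: float  # S/m
    sigma_rel_uncertainty: float
    monitoring: dict
    seed: int
    raw: dict = dc_field(default_factory=dict)


def default_config_dict() -> dict:
    """Shipped defaults: nominal geometry, calibration-shaped circuit, the
    standard uncertainty table, and the operating constants."""
    return {
        "geometry": {},
        "circuit": None,  # default chamber circuit
        "network": {"n_wells": 1, "connection": "single",
                    "shunt_resistance": 0.0},
        "uq": {
            "order": 4,
            "parameters": [
                {"name": "electrode_height_1", "lower": 0.01, "upper": 1.5},
                {"name": "electrode_height_2", "lower": 0.01, "upper": 1.5},
                {"name": "bottom_length", "lower": 21.0, "upper": 22.3},
                {"name": "electrode_spacing", "lower": 23.0, "upper": 25.0},
                {"name": "meniscus_decay", "lower": 1.95, "upper": 2.05},
                {"name": "meniscus_height_max", "lower": 1.8, "upper": 2.5},
                {"name": "medium_volume", "lower": 3.4, "upper": 3.6},
            ],
        },
        "processing": {
            "truncation_ratio": 0.1,
            "linearity_limit": 0.25,
            "eis_amplitude": 0.025,
        },
        "medium": {
            "conductivity": 1.38,
            "alpha_conductivity": 0.02,
            "sigma_rel_uncertainty": 0.02,
        },
        "monitoring": {
            "deviation_alarm": 0.03,
            "dc_offset_alarm": 0.020,
        },
        "seed": 42,
    }


_KNOWN_TOP = {"geometry", "circuit", "network", "uq", "processing", "medium",
              "monitoring", "seed"}


def load_config(path_or_dict) -> Config:
    """Load and validate a YAML configuration (or an equivalent dict)."""
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    unknown = set(user) - _KNOWN_TOP
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    cfg = default_config_dict()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val

    geo_kwargs = cfg["geometry"] or {}
    bad = set(geo_kwargs) - set(ChamberGeometry.__dataclass_fields__)
    if bad:
        raise ValueError(f"unknown geometry fields: {sorted(bad)}")
    geometry = ChamberGeometry(**geo_kwargs)

    circuit = (
        default_chamber_circuit()
        if cfg["circuit"] is None
        else circuit_from_dict(cfg["circuit"])
    )
    network = NetworkConfig(**cfg["network"])

    params = []
    for p in cfg["uq"]["parameters"]:
        extra = set(p) - {"name", "lower", "upper", "distribution"}
        if extra:
            raise ValueError(f"unknown uq parameter fields: {sorted(extra)}")
        params.append(UncertainParameter(**p))

    proc = cfg["processing"]
    if not (0 <= proc["truncation_ratio"] < 1):
        raise ValueError("processing.truncation_ratio must be in [0, 1)")
    med = cfg["medium"]
    if med["conductivity"] <= 0 or med["alpha_conductivity"] <= 0:
        raise ValueError("medium conductivity and alpha must be > 0")

    return Config(
        geometry=geometry,
        circuit=circuit,
        network=network,
        uq_parameters=params,
        uq_order=int(cfg["uq"]["order"]),
        truncation_ratio=float(proc["truncation_ratio"]),
        linearity_limit=float(proc["linearity_limit"]),
        alpha_conductivity=float(med["alpha_conductivity"]),
        conductivity=float(med["conductivity"]),
        sigma_rel_uncertainty=float(med["sigma_rel_uncertainty"]),
        monitoring=dict(cfg["monitoring"]),
        seed=int(cfg["seed"]),
        raw=cfg,
    )
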