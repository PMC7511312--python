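"""YAML parameter files with bench units.

An electro-model config states cell and pulse parameters in the units a
protocol sheet prints (um, uF/cm^2, mS/cm, kV/cm, ns, ml/min, ml); this
module converts them to the SI quantities the model takes. All keys are
optional and default to the reference Haematococcus treatment conditions.

Example file::

    cell:
      radius_um: 14
      membrane_capacitance_uf_per_cm2: 1
      cytoplasm_conductivity_ms_per_cm: 10
      medium_conductivity_ms_per_cm: 1.6
    pulse:
      field_kv_per_cm: 40
      duration_ns: 25
      repetition_hz: 4
      pulse_count: 32
      flow_ml_per_min: 3.75
      chamber_volume_ml: 0.5
    model:
      threshold_v: 1.0
      schwan_factor: 1.0
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import yaml

from . import units
from .electro import CellElectricalModel, PulseProtocol
from .errors import ConfigurationError

__all__ = ["ElectroConfig", "load_electro_config"]


@dataclass(frozen=True)
class ElectroConfig:
    cell: CellElectricalModel
    pulse: PulseProtocol
    threshold_v: float = 1.0
    schwan_factor: float = 1.0
    tau_c_s: Optional[float] = None  # published override; None -> compute


_CELL_DEFAULTS = {
    "radius_um": 14.0,
    "membrane_capacitance_uf_per_cm2": 1.0,
    "cytoplasm_conductivity_ms_per_cm": 10.0,
    "medium_conductivity_ms_per_cm": 1.6,
}
_PULSE_DEFAULTS = {
    "field_kv_per_cm": 40.0,
    "duration_ns": 25.0,
    "repetition_hz": 4.0,
    "pulse_count": 32,
    "flow_ml_per_min": 3.75,
    "chamber_volume_ml": 0.5,
    "density_g_per_cm3": 1.0,
}
_MODEL_DEFAULTS = {"threshold_v": 1.0, "schwan_factor": 1.0, "tau_c_s": None}


def _merged(section: dict, defaults: dict, name: str) -> dict:
    unknown = set(section) - set(defaults)
    if unknown:
        raise ConfigurationError(f"unknown keys in [{name}] section: {sorted(unknown)}")
    return {**defaults, **section}


def load_electro_config(path=None, text: Optional[str] = None) -> ElectroConfig:
    """Load an electro-model config from a YAML file or string."""
    if text is None:
        if path is None:
            raw = {}
        else:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
    else:
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    cell_raw = _merged(raw.get("cell", {}) or {}, _CELL_DEFAULTS, "cell")
    pulse_raw = _merged(raw.get("pulse", {}) or {}, _PULSE_DEFAULTS, "pulse")
    model_raw = _merged(raw.get("model", {}) or {}, _MODEL_DEFAULTS, "model")

    cell = CellElectricalModel(
        radius_m=units.um(cell_raw["radius_um"]),
        membrane_capacitance_f_per_m2=units.uf_per_cm2(
            cell_raw["membrane_capacitance_uf_per_cm2"]
        ),
        cytoplasm_conductivity_s_per_m=units.ms_per_cm(
            cell_raw["cytoplasm_conductivity_ms_per_cm"]
        ),
        medium_conductivity_s_per_m=units.ms_per_cm(
            cell_raw["medium_conductivity_ms_per_cm"]
        ),
    )
    pulse = PulseProtocol(
        field_v_per_m=units.kv_per_cm(pulse_raw["field_kv_per_cm"]),
        duration_s=units.ns(pulse_raw["duration_ns"]),
        medium_conductivity_s_per_m=cell.medium_conductivity_s_per_m,
        repetition_hz=pulse_raw["repetition_hz"],
        pulse_count=pulse_raw["pulse_count"],
        flow_rate_m3_per_s=units.ml_per_min(pulse_raw["flow_ml_per_min"]),
        chamber_volume_m3=units.ml(pulse_raw["chamber_volume_ml"]),
        density_kg_per_m3=1000.0 * pulse_raw["density_g_per_cm3"],
    )
    return ElectroConfig(
        cell=cell,
        pulse=pulse,
        threshold_v=float(model_raw["threshold_v"]),
        schwan_factor=float(model_raw["schwan_factor"]),
        tau_c_s=model_raw["tau_c_s"],
    )
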