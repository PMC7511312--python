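"""Unit conversion helpers.

All public model interfaces take SI units (m, s, V/m, S/m, F/m^2). Laboratory
protocols are usually written in kV/cm, ns, mS/cm, um and uF/cm^2; these
helpers convert such bench units to SI so that parameter files can state
values exactly as a protocol sheet prints them.
"""

from __future__ import annotations

# field strength
KV_PER_CM = 1e5  # 1 kV/cm = 1e5 V/m

# conductivity
MS_PER_CM = 0.1  # 1 mS/cm = 0.1 S/m

# membrane capacitance
UF_PER_CM2 = 1e-2  # 1 uF/cm^2 = 0.01 F/m^2

NS = 1e-9
UM = 1e-6
ML = 1e-6  # m^3
ML_PER_MIN = 1e-6 / 60.0  # m^3/s


def kv_per_cm(x: float) -> float:
    """Field strength, kV/cm -> V/m."""
    return x * KV_PER_CM


def ms_per_cm(x: float) -> float:
    """Conductivity, mS/cm -> S/m."""
    return x * MS_PER_CM


def uf_per_cm2(x: float) -> float:
    """Membrane capacitance per area, uF/cm^2 -> F/m^2."""
    return x * UF_PER_CM2


def ns(x: float) -> float:
    """Time, ns -> s."""
    return x * NS


def um(x: float) -> float:
    """Length, um -> m."""
    return x * UM


def ml(x: float) -> float:
    """Volume, ml -> m^3."""
    return x * ML


def ml_per_min(x: float) -> float:
    """Flow rate, ml/min -> m^3/s."""
    return x * ML_PER_MIN
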