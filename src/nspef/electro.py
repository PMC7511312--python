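"""Single-shell membrane-charging model for a spherical cell in a uniform field.

A step field pulse of strength ``E`` applied to a suspension charges the
plasma membrane of a spherical cell of radius ``a`` according to the
Schwan-type charging law

    V_m(theta, t) = E * a * cos(theta) * (1 - exp(-t / tau_C))

with the charging time constant

    tau_C = a * C_m * (1 / sigma_i + 1 / (2 * sigma_e))

where ``C_m`` is the membrane capacitance per unit area and ``sigma_i`` /
``sigma_e`` the cytoplasm and external-medium conductivities. ``theta`` is
the azimuth angle measured from the field-axis pole. The classical
steady-state relation carries an additional geometric factor 3/2; this
module defaults to a factor of 1 (``schwan_factor=1.0``) so that the model
matches the charging-curve convention used for the Haematococcus treatment
conditions, and exposes the textbook 1.5 variant as an option.

Beyond the charging law the module provides:

* a voltage-threshold permeabilisation geometry — the largest azimuth
  ``theta*`` at which ``V_m`` reaches a threshold (~1 V for irreversible
  electroporation), the covered fraction of the great-circle circumference
  through the field axis, and the covered spherical-cap surface fraction;
* rectangular-pulse Joule dosimetry — per-pulse energy density
  ``w1 = sigma_e * E^2 * dt`` and specific treatment energy
  ``W = N * w1 / rho``;
* the mean pulse count experienced by a cell transiting a continuous-flow
  treatment chamber, ``N = f * V_ch / Q``.

Angles are degrees at every public interface; radians are used internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .errors import ConfigurationError, ValidationError

__all__ = [
    "CellElectricalModel",
    "ChargingConstants",
    "PulseProtocol",
    "ChargingCurve",
    "PermeabilisationSummary",
    "DoseReport",
    "charging_time_constant",
    "transmembrane_voltage",
    "charging_curve",
    "threshold_azimuth",
    "circumference_coverage",
    "sphere_cap_coverage",
    "permeabilisation_summary",
    "specific_energy",
    "residence_pulse_count",
    "HAEMATOCOCCUS_CELL",
    "PRINTED_TAU_C_S",
    "DEFAULT_THRESHOLD_V",
]

#: Default irreversible-electroporation threshold (V).
DEFAULT_THRESHOLD_V = 1.0

#: Charging time constant printed for the reference parameter set (s). Direct
#: evaluation of the charging-constant formula with the same nominal
#: parameters gives ~5.78e-7 s (a ~3.5% gap attributable to a unit misprint
#: in the source parameter list); the printed value is kept available so
#: published charging curves can be reproduced verbatim.
PRINTED_TAU_C_S = 5.98e-7


@dataclass(frozen=True)
class CellElectricalModel:
    """Electrical description of a spherical cell.

    Parameters
    ----------
    radius_m:
        Cell radius ``a`` in metres. Must lie within 1e-7–1e-3 m.
    membrane_capacitance_f_per_m2:
        Membrane capacitance per unit area ``C_m`` (F/m^2). A plasma
        membrane is typically ~0.01 F/m^2 (1 uF/cm^2).
    cytoplasm_conductivity_s_per_m:
        Internal conductivity ``sigma_i`` (S/m).
    medium_conductivity_s_per_m:
        External medium conductivity ``sigma_e`` (S/m).
    """

    radius_m: float
    membrane_capacitance_f_per_m2: float
    cytoplasm_conductivity_s_per_m: float
    medium_conductivity_s_per_m: float

    def __post_init__(self) -> None:
        for name in (
            "radius_m",
            "membrane_capacitance_f_per_m2",
            "cytoplasm_conductivity_s_per_m",
            "medium_conductivity_s_per_m",
        ):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValidationError(f"{name} must be strictly positive, got {value!r}")
        if not (1e-7 <= self.radius_m <= 1e-3):
            raise ValidationError(
                f"radius_m={self.radius_m!r} outside the plausible cell range 1e-7–1e-3 m"
            )


@dataclass(frozen=True)
class ChargingConstants:
    """Derived charging constants for one cell (and optionally one field).

    ``beta_dispersion_hz`` is defined as ``1 / tau_c_s`` — the convention
    used alongside the charging law here (not the angular-frequency variant
    ``1 / (2 pi tau)``). ``polar_voltage_v`` is the steady-state voltage at
    the pole, ``E * a``; it is ``None`` until a field strength is supplied.
    """

    tau_c_s: float
    beta_dispersion_hz: float
    polar_voltage_v: Optional[float] = None

    def __post_init__(self) -> None:
        if self.tau_c_s <= 0:
            raise ValidationError("tau_c_s must be positive")
        if self.polar_voltage_v is not None and self.polar_voltage_v < 0:
            raise ValidationError("polar_voltage_v must be non-negative")


@dataclass(frozen=True)
class PulseProtocol:
    """One nsPEF treatment protocol.

    ``flow_rate_m3_per_s`` and ``chamber_volume_m3`` are only needed for
    continuous-flow residence-time pulse counting.
    """

    field_v_per_m: float
    duration_s: float
    medium_conductivity_s_per_m: float
    repetition_hz: Optional[float] = None
    pulse_count: Optional[int] = None
    flow_rate_m3_per_s: Optional[float] = None
    chamber_volume_m3: Optional[float] = None
    density_kg_per_m3: float = 1000.0

    def __post_init__(self) -> None:
        if self.field_v_per_m <= 0:
            raise ValidationError("field_v_per_m must be positive")
        if self.duration_s <= 0:
            raise ValidationError("duration_s must be positive")
        if self.medium_conductivity_s_per_m <= 0:
            raise ValidationError("medium_conductivity_s_per_m must be positive")
        if self.density_kg_per_m3 <= 0:
            raise ValidationError("density_kg_per_m3 must be positive")
        if self.pulse_count is not None:
            if self.pulse_count < 0 or int(self.pulse_count) != self.pulse_count:
                raise ValidationError("pulse_count must be a non-negative integer")


@dataclass(frozen=True)
class ChargingCurve:
    """Transmembrane voltage sampled on an azimuth x time grid.

    ``v_m`` has shape ``(len(theta_deg), len(t_s))``. ``above_threshold``
    flags entries where ``V_m`` exceeds the electroporation threshold; those
    voltages are reported unclamped but are hypothetical — in a real cell
    the membrane breaks down and the voltage collapses.
    """

    theta_deg: np.ndarray
    t_s: np.ndarray
    v_m: np.ndarray
    above_threshold: np.ndarray
    threshold_v: float = DEFAULT_THRESHOLD_V


@dataclass(frozen=True)
class PermeabilisationSummary:
    """Threshold-crossing geometry at a fixed time after pulse onset.

    ``theta_star_deg`` is the largest azimuth at which the threshold is
    reached, or ``None`` when it is reached nowhere ("unreached").
    ``circumference_fraction`` is the fraction of the great circle through
    the field axis that lies above threshold (both polar arcs);
    ``cap_fraction`` is the corresponding fraction of the sphere surface
    (both caps).
    """

    threshold_v: float
    time_s: float
    theta_star_deg: Optional[float]
    circumference_fraction: float
    cap_fraction: float

    @property
    def reached(self) -> bool:
        return self.theta_star_deg is not None


@dataclass(frozen=True)
class DoseReport:
    """Joule dose of one pulse train.

    ``specific_energy_j_per_kg`` is ``N * w1 / rho``; the conventional
    report scale for PEF treatments is J/g (``specific_energy_j_per_g``).
    """

    per_pulse_energy_density_j_per_m3: float
    specific_energy_j_per_kg: float
    pulse_count: int

    @property
    def specific_energy_j_per_g(self) -> float:
        return self.specific_energy_j_per_kg / 1000.0


def charging_time_constant(
    cell: CellElectricalModel, field_v_per_m: Optional[float] = None
) -> ChargingConstants:
    """Charging time constant, beta-dispersion frequency and polar voltage.

    tau_C = a * C_m * (1/sigma_i + 1/(2 sigma_e)); f_c = 1/tau_C.
    The polar voltage ``E*a`` is filled in only when a field is given.
    """
    tau = cell.radius_m * cell.membrane_capacitance_f_per_m2 * (
        1.0 / cell.cytoplasm_conductivity_s_per_m
        + 1.0 / (2.0 * cell.medium_conductivity_s_per_m)
    )
    polar = None
    if field_v_per_m is not None:
        if field_v_per_m < 0:
            raise ValidationError("field_v_per_m must be non-negative")
        polar = field_v_per_m * cell.radius_m
    return ChargingConstants(tau_c_s=tau, beta_dispersion_hz=1.0 / tau, polar_voltage_v=polar)


def transmembrane_voltage(
    cell: CellElectricalModel,
    field_v_per_m: float,
    theta_deg: Union[float, Sequence[float], np.ndarray],
    t_s: Union[float, Sequence[float], np.ndarray],
    *,
    tau_c_s: Optional[float] = None,
    schwan_factor: float = 1.0,
) -> np.ndarray:
    """Induced transmembrane voltage ``V_m(theta, t)``.

    Accepts scalars or arrays for ``theta_deg`` (0–180 deg) and ``t_s``
    (broadcast together). Values at theta > 90 deg come out negative — the
    two hemispheres polarise with opposite sign. ``tau_c_s`` overrides the
    time constant computed from the cell (e.g. to use a published value);
    ``schwan_factor`` switches to the textbook 3/2 steady-state factor.
    """
    theta = np.asarray(theta_deg, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be non-negative")
    if np.any((theta < 0) | (theta > 180)):
        raise ValidationError("theta_deg must lie in [0, 180]")
    if tau_c_s is None:
        tau_c_s = charging_time_constant(cell).tau_c_s
    if tau_c_s <= 0:
        raise ValidationError("tau_c_s must be positive")
    vm = (
        schwan_factor
        * field_v_per_m
        * cell.radius_m
        * np.cos(np.deg2rad(theta))
        * (1.0 - np.exp(-t / tau_c_s))
    )
    return vm


def charging_curve(
    cell: CellElectricalModel,
    field_v_per_m: float,
    theta_deg: Sequence[float],
    t_s: Sequence[float],
    *,
    threshold_v: float = DEFAULT_THRESHOLD_V,
    tau_c_s: Optional[float] = None,
    schwan_factor: float = 1.0,
) -> ChargingCurve:
    """Sample ``V_m`` on an azimuth x time grid with threshold flags.

    Both grids must be non-empty and sorted ascending. Voltages above the
    threshold are flagged, not clamped (they are hypothetical: the membrane
    would break down by electroporation before reaching them).
    """
    theta = np.asarray(theta_deg, dtype=float)
    t = np.asarray(t_s, dtype=float)
    if theta.size == 0 or t.size == 0:
        raise ValidationError("azimuth and time grids must be non-empty")
    if np.any(np.diff(theta) < 0) or np.any(np.diff(t) < 0):
        raise ValidationError("grids must be sorted ascending")
    vm = transmembrane_voltage(
        cell,
        field_v_per_m,
        theta[:, None],
        t[None, :],
        tau_c_s=tau_c_s,
        schwan_factor=schwan_factor,
    )
    return ChargingCurve(
        theta_deg=theta,
        t_s=t,
        v_m=vm,
        above_threshold=vm > threshold_v,
        threshold_v=threshold_v,
    )


def threshold_azimuth(
    cell: CellElectricalModel,
    field_v_per_m: float,
    t_s: float,
    threshold_v: float = DEFAULT_THRESHOLD_V,
    *,
    tau_c_s: Optional[float] = None,
    schwan_factor: float = 1.0,
) -> Optional[float]:
    """Largest azimuth (degrees) at which ``V_m`` reaches the threshold.

    Inverts the charging law:
    ``theta* = arccos(V_th / (E a (1 - exp(-t/tau_C))))``. Returns ``None``
    when the polar voltage at time ``t`` is still below the threshold
    (threshold unreached anywhere on the sphere).
    """
    if t_s <= 0:
        raise ValidationError("time must be positive")
    if threshold_v <= 0:
        raise ValidationError("threshold_v must be positive")
    vpole = float(
        transmembrane_voltage(
            cell, field_v_per_m, 0.0, t_s, tau_c_s=tau_c_s, schwan_factor=schwan_factor
        )
    )
    if vpole < threshold_v:
        return None
    return math.degrees(math.acos(threshold_v / vpole))


def circumference_coverage(theta_star_deg: float) -> float:
    """Fraction of the field-axis great circle above threshold.

    Both polar arcs count (the field polarises both hemispheres), so
    ``c = 4 theta* / 360``; theta* = 90 deg covers the full circumference.
    """
    if not (0 < theta_star_deg <= 90):
        raise ValidationError("theta_star_deg must lie in (0, 90]")
    return 4.0 * theta_star_deg / 360.0


def sphere_cap_coverage(theta_star_deg: float) -> float:
    """Fraction of the sphere surface above threshold (both polar caps).

    One cap of half-angle theta* has area fraction ``(1 - cos theta*)/2``;
    with both caps, ``s = 1 - cos theta*``.
    """
    if not (0 <= theta_star_deg <= 90):
        raise ValidationError("theta_star_deg must lie in [0, 90]")
    return 1.0 - math.cos(math.radians(theta_star_deg))


def permeabilisation_summary(
    cell: CellElectricalModel,
    field_v_per_m: float,
    t_s: float,
    threshold_v: float = DEFAULT_THRESHOLD_V,
    *,
    tau_c_s: Optional[float] = None,
    schwan_factor: float = 1.0,
) -> PermeabilisationSummary:
    """Threshold azimuth plus circumference and cap coverage at time ``t``."""
    theta_star = threshold_azimuth(
        cell,
        field_v_per_m,
        t_s,
        threshold_v,
        tau_c_s=tau_c_s,
        schwan_factor=schwan_factor,
    )
    if theta_star is None:
        circ, cap = 0.0, 0.0
    else:
        circ = circumference_coverage(theta_star)
        cap = sphere_cap_coverage(theta_star)
    return PermeabilisationSummary(
        threshold_v=threshold_v,
        time_s=t_s,
        theta_star_deg=theta_star,
        circumference_fraction=circ,
        cap_fraction=cap,
    )


def specific_energy(protocol: PulseProtocol) -> DoseReport:
    """Rectangular-pulse Joule dose of a pulse train.

    Per-pulse energy density ``w1 = sigma_e E^2 dt`` (J/m^3) and specific
    treatment energy ``W = N w1 / rho`` (J/kg). No temperature correction.
    """
    if protocol.pulse_count is None:
        raise ConfigurationError("specific_energy requires pulse_count on the protocol")
    w1 = (
        protocol.medium_conductivity_s_per_m
        * protocol.field_v_per_m**2
        * protocol.duration_s
    )
    w = protocol.pulse_count * w1 / protocol.density_kg_per_m3
    return DoseReport(
        per_pulse_energy_density_j_per_m3=w1,
        specific_energy_j_per_kg=w,
        pulse_count=int(protocol.pulse_count),
    )


def residence_pulse_count(protocol: PulseProtocol) -> int:
    """Mean pulse count for a cell transiting a continuous-flow chamber.

    ``N = round(f * V_ch / Q)``: residence time ``V_ch / Q`` multiplied by
    the repetition frequency. Requires flow rate, chamber volume and
    repetition frequency on the protocol.
    """
    if (
        protocol.flow_rate_m3_per_s is None
        or protocol.chamber_volume_m3 is None
        or protocol.repetition_hz is None
    ):
        raise ConfigurationError(
            "residence_pulse_count requires flow_rate_m3_per_s, chamber_volume_m3 "
            "and repetition_hz"
        )
    if protocol.flow_rate_m3_per_s <= 0 or protocol.chamber_volume_m3 <= 0:
        raise ValidationError("flow rate and chamber volume must be positive")
    if protocol.repetition_hz < 0:
        raise ValidationError("repetition_hz must be non-negative")
    return int(round(protocol.repetition_hz * protocol.chamber_volume_m3 / protocol.flow_rate_m3_per_s))


#: Reference Haematococcus pluvialis cell: a = 14 um, C_m = 1 uF/cm^2,
#: sigma_i = 10 mS/cm, sigma_e = 1.6 mS/cm.
HAEMATOCOCCUS_CELL = CellElectricalModel(
    radius_m=14e-6,
    membrane_capacitance_f_per_m2=1e-2,
    cytoplasm_conductivity_s_per_m=1.0,
    medium_conductivity_s_per_m=0.16,
)


def reference_protocol(duration_ns: float, *, pulse_count: int = 32) -> PulseProtocol:
    """Treatment protocol used for the reference conditions.

    40 kV/cm field, 1.6 mS/cm medium, 4 Hz repetition, 3.75 ml/min flow
    through a 0.5 ml chamber (which yields an average of 32 pulses per
    cell), suspension density 1 g/cm^3.
    """
    return PulseProtocol(
        field_v_per_m=4e6,
        duration_s=duration_ns * 1e-9,
        medium_conductivity_s_per_m=0.16,
        repetition_hz=4.0,
        pulse_count=pulse_count,
        flow_rate_m3_per_s=3.75e-6 / 60.0,
        chamber_volume_m3=0.5e-6,
        density_kg_per_m3=1000.0,
    )
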