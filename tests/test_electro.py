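"""Membrane-charging model: charging constants, voltage law, geometry, dose."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nspef import units
from nspef.electro import (
    CellElectricalModel,
    PRINTED_TAU_C_S,
    PulseProtocol,
    charging_curve,
    charging_time_constant,
    circumference_coverage,
    permeabilisation_summary,
    reference_protocol,
    residence_pulse_count,
    specific_energy,
    sphere_cap_coverage,
    threshold_azimuth,
    transmembrane_voltage,
)
from nspef.errors import ConfigurationError, ValidationError

FIELD = 4e6  # 40 kV/cm


class TestChargingTimeConstant:
    def test_reference_cell_matches_published_value(self, haem_cell):
        """Direct evaluation lands within 5% of the published 5.98e-7 s."""
        tau = charging_time_constant(haem_cell).tau_c_s
        assert tau == pytest.approx(PRINTED_TAU_C_S, rel=0.05)

    def test_hand_evaluated_example(self):
        cell = CellElectricalModel(10e-6, 0.01, 1.0, 0.5)
        assert charging_time_constant(cell).tau_c_s == pytest.approx(2.0e-7)

    @pytest.mark.parametrize("attr", ["radius_m", "membrane_capacitance_f_per_m2"])
    def test_linear_in_radius_and_capacitance(self, haem_cell, attr):
        doubled = CellElectricalModel(
            **{
                f: getattr(haem_cell, f) * (2 if f == attr else 1)
                for f in (
                    "radius_m",
                    "membrane_capacitance_f_per_m2",
                    "cytoplasm_conductivity_s_per_m",
                    "medium_conductivity_s_per_m",
                )
            }
        )
        assert charging_time_constant(doubled).tau_c_s == pytest.approx(
            2 * charging_time_constant(haem_cell).tau_c_s
        )

    @given(factor=st.floats(1.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_decreasing_in_conductivities(self, factor):
        base = CellElectricalModel(14e-6, 1e-2, 1.0, 0.16)
        tau0 = charging_time_constant(base).tau_c_s
        for attr in ("cytoplasm_conductivity_s_per_m", "medium_conductivity_s_per_m"):
            kwargs = {
                "radius_m": base.radius_m,
                "membrane_capacitance_f_per_m2": base.membrane_capacitance_f_per_m2,
                "cytoplasm_conductivity_s_per_m": base.cytoplasm_conductivity_s_per_m,
                "medium_conductivity_s_per_m": base.medium_conductivity_s_per_m,
            }
            kwargs[attr] *= factor
            assert charging_time_constant(CellElectricalModel(**kwargs)).tau_c_s < tau0

    def test_beta_dispersion_is_reciprocal_tau(self, haem_cell):
        k = charging_time_constant(haem_cell)
        assert k.beta_dispersion_hz == pytest.approx(1.0 / k.tau_c_s)

    def test_polar_voltage_needs_field(self, haem_cell):
        assert charging_time_constant(haem_cell).polar_voltage_v is None
        assert charging_time_constant(haem_cell, FIELD).polar_voltage_v == pytest.approx(56.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(radius_m=-14e-6, membrane_capacitance_f_per_m2=1e-2,
                 cytoplasm_conductivity_s_per_m=1.0, medium_conductivity_s_per_m=0.16),
            dict(radius_m=14e-6, membrane_capacitance_f_per_m2=0.0,
                 cytoplasm_conductivity_s_per_m=1.0, medium_conductivity_s_per_m=0.16),
            dict(radius_m=5e-3, membrane_capacitance_f_per_m2=1e-2,
                 cytoplasm_conductivity_s_per_m=1.0, medium_conductivity_s_per_m=0.16),
        ],
    )
    def test_invalid_cells_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            CellElectricalModel(**kwargs)


class TestTransmembraneVoltage:
    def test_zero_at_time_zero_and_equator(self, haem_cell):
        assert transmembrane_voltage(haem_cell, FIELD, 37.0, 0.0) == 0.0
        assert transmembrane_voltage(haem_cell, FIELD, 90.0, 1e-6) == pytest.approx(0.0, abs=1e-12)

    def test_steady_state_polar_limit(self, haem_cell):
        """V_m -> E*a = 56 V at the pole; within 1e-6 relative at t = 20 tau."""
        tau = charging_time_constant(haem_cell).tau_c_s
        vm = transmembrane_voltage(haem_cell, FIELD, 0.0, 20 * tau)
        assert vm == pytest.approx(56.0, rel=1e-6)

    def test_published_curve_value_at_25ns(self, haem_cell):
        """Polar voltage ~2.3 V at 25 ns with the published time constant."""
        vm = transmembrane_voltage(haem_cell, FIELD, 0.0, 25e-9, tau_c_s=PRINTED_TAU_C_S)
        assert vm == pytest.approx(2.3, abs=0.05)

    def test_antisymmetric_about_equator(self, haem_cell):
        theta = np.array([0.0, 15.0, 40.0, 75.0])
        v_north = transmembrane_voltage(haem_cell, FIELD, theta, 30e-9)
        v_south = transmembrane_voltage(haem_cell, FIELD, 180.0 - theta, 30e-9)
        np.testing.assert_allclose(v_south, -v_north, atol=1e-12)

    def test_schwan_factor_scales_voltage(self, haem_cell):
        v1 = transmembrane_voltage(haem_cell, FIELD, 20.0, 30e-9)
        v15 = transmembrane_voltage(haem_cell, FIELD, 20.0, 30e-9, schwan_factor=1.5)
        assert v15 == pytest.approx(1.5 * v1)

    def test_negative_time_rejected(self, haem_cell):
        with pytest.raises(ValidationError):
            transmembrane_voltage(haem_cell, FIELD, 0.0, -1e-9)


class TestChargingCurve:
    def test_equals_pointwise_voltage(self, haem_cell):
        """Grid evaluation must agree with the closed form point by point."""
        theta = np.arange(0.0, 91.0, 5.0)
        t = np.linspace(0.0, 80e-9, 33)
        curve = charging_curve(haem_cell, FIELD, theta, t)
        for i, th in enumerate(theta):
            for j, tj in enumerate(t):
                assert curve.v_m[i, j] == pytest.approx(
                    float(transmembrane_voltage(haem_cell, FIELD, th, tj)), abs=1e-12
                )

    def test_flags_monotone_in_time(self, haem_cell):
        curve = charging_curve(
            haem_cell, FIELD, np.arange(0.0, 91.0, 10.0), np.linspace(0, 100e-9, 51)
        )
        diffs = np.diff(curve.above_threshold.astype(int), axis=1)
        assert (diffs >= 0).all()

    def test_single_point_grid(self, haem_cell):
        curve = charging_curve(haem_cell, FIELD, [0.0], [0.0])
        assert curve.v_m.shape == (1, 1)
        assert curve.v_m[0, 0] == 0.0
        assert not curve.above_threshold[0, 0]

    @pytest.mark.parametrize("theta,t", [([], [0.0]), ([0.0], []), ([10.0, 0.0], [0.0])])
    def test_bad_grids_rejected(self, haem_cell, theta, t):
        with pytest.raises(ValidationError):
            charging_curve(haem_cell, FIELD, theta, t)


class TestPermeabilisationGeometry:
    def test_threshold_azimuth_published_conditions(self, haem_cell):
        """~77 deg at 50 ns and ~64 deg at 25 ns with the published tau."""
        t50 = threshold_azimuth(haem_cell, FIELD, 50e-9, tau_c_s=PRINTED_TAU_C_S)
        t25 = threshold_azimuth(haem_cell, FIELD, 25e-9, tau_c_s=PRINTED_TAU_C_S)
        assert t50 == pytest.approx(77.1, abs=0.5)
        assert 64.0 <= t25 <= 65.0

    def test_unreached_below_threshold(self, haem_cell):
        assert threshold_azimuth(haem_cell, 1e4, 50e-9) is None

    def test_strictly_increasing_in_time(self, haem_cell):
        times = np.array([15, 20, 40, 80, 160]) * 1e-9  # below ~11 ns the 1 V threshold is unreached
        stars = [threshold_azimuth(haem_cell, FIELD, t) for t in times]
        assert all(a < b for a, b in zip(stars, stars[1:]))

    @pytest.mark.parametrize("theta,expected", [(90.0, 1.0), (45.0, 0.5)])
    def test_circumference_coverage_values(self, theta, expected):
        assert circumference_coverage(theta) == pytest.approx(expected)

    def test_circumference_two_thirds_at_25ns(self, haem_cell):
        """25 ns coverage ~0.71-0.72, the 'around 2/3' regime."""
        star = threshold_azimuth(haem_cell, FIELD, 25e-9)
        assert circumference_coverage(star) == pytest.approx(0.72, abs=0.02)
        assert circumference_coverage(star) >= 2 / 3

    @pytest.mark.parametrize("theta,expected", [(90.0, 1.0), (0.0, 0.0), (60.0, 0.5)])
    def test_cap_coverage_values(self, theta, expected):
        assert sphere_cap_coverage(theta) == pytest.approx(expected)

    @pytest.mark.parametrize("theta", [-5.0, 0.0, 95.0])
    def test_circumference_rejects_out_of_range(self, theta):
        with pytest.raises(ValidationError):
            circumference_coverage(theta)

    def test_summary_monotone_in_duration(self, haem_cell):
        s25 = permeabilisation_summary(haem_cell, FIELD, 25e-9)
        s50 = permeabilisation_summary(haem_cell, FIELD, 50e-9)
        assert s25.reached and s50.reached
        assert s25.circumference_fraction < s50.circumference_fraction
        assert s25.cap_fraction < s50.cap_fraction


class TestDoseAndFlow:
    def test_published_specific_energies(self):
        """32 pulses at 40 kV/cm in 1.6 mS/cm: ~2 J/g at 25 ns, ~4 J/g at 50 ns."""
        w25 = specific_energy(reference_protocol(25)).specific_energy_j_per_g
        w50 = specific_energy(reference_protocol(50)).specific_energy_j_per_g
        assert w25 == pytest.approx(2.0, rel=0.05)
        assert w50 == pytest.approx(4.0, rel=0.05)

    def test_zero_pulses_zero_dose(self):
        assert specific_energy(reference_protocol(25, pulse_count=0)).specific_energy_j_per_kg == 0.0

    def test_scaling_laws(self):
        """W linear in N, dt, sigma_e; quadratic in E."""
        base = PulseProtocol(
            field_v_per_m=4e6, duration_s=25e-9,
            medium_conductivity_s_per_m=0.16, pulse_count=32,
        )
        w0 = specific_energy(base).specific_energy_j_per_kg

        def scaled(**kw):
            merged = dict(
                field_v_per_m=base.field_v_per_m, duration_s=base.duration_s,
                medium_conductivity_s_per_m=base.medium_conductivity_s_per_m,
                pulse_count=base.pulse_count,
            )
            merged.update(kw)
            return specific_energy(PulseProtocol(**merged)).specific_energy_j_per_kg

        assert scaled(pulse_count=64) == pytest.approx(2 * w0)
        assert scaled(duration_s=50e-9) == pytest.approx(2 * w0)
        assert scaled(medium_conductivity_s_per_m=0.32) == pytest.approx(2 * w0)
        assert scaled(field_v_per_m=8e6) == pytest.approx(4 * w0)

    def test_residence_pulse_count_reference_conditions(self):
        """0.5 ml chamber at 3.75 ml/min and 4 Hz: 32 pulses per cell."""
        assert residence_pulse_count(reference_protocol(25)) == 32

    def test_flow_scaling_and_zero_frequency(self):
        proto = reference_protocol(25)
        doubled_q = PulseProtocol(
            field_v_per_m=proto.field_v_per_m, duration_s=proto.duration_s,
            medium_conductivity_s_per_m=proto.medium_conductivity_s_per_m,
            repetition_hz=proto.repetition_hz, pulse_count=proto.pulse_count,
            flow_rate_m3_per_s=2 * proto.flow_rate_m3_per_s,
            chamber_volume_m3=proto.chamber_volume_m3,
        )
        assert residence_pulse_count(doubled_q) == 16
        zero_f = PulseProtocol(
            field_v_per_m=proto.field_v_per_m, duration_s=proto.duration_s,
            medium_conductivity_s_per_m=proto.medium_conductivity_s_per_m,
            repetition_hz=0.0, pulse_count=proto.pulse_count,
            flow_rate_m3_per_s=proto.flow_rate_m3_per_s,
            chamber_volume_m3=proto.chamber_volume_m3,
        )
        assert residence_pulse_count(zero_f) == 0

    def test_missing_flow_parameters_is_configuration_error(self):
        proto = PulseProtocol(
            field_v_per_m=4e6, duration_s=25e-9, medium_conductivity_s_per_m=0.16
        )
        with pytest.raises(ConfigurationError):
            residence_pulse_count(proto)


def test_unit_helpers_round_trip():
    assert units.kv_per_cm(40) == 4e6
    assert units.ms_per_cm(1.6) == pytest.approx(0.16)
    assert units.uf_per_cm2(1) == pytest.approx(1e-2)
    assert units.ml_per_min(3.75) == pytest.approx(6.25e-8)
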