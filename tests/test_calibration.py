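"""Sensor-physics arithmetic: divider, thermistor, FSR, unit conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insolekit.calibration import (
    CalibrationFit,
    DividerConfig,
    FSRForceModel,
    OpenCircuitError,
    SensorGeometry,
    ThermistorModel,
    active_area,
    adc_to_voltage,
    fit_exponential_calibration,
    force_from_pressure,
    force_from_resistance,
    mass_from_force,
    resistance_from_force,
    resistance_from_voltage,
    temperature_from_adc,
    temperature_from_resistance,
    thermistor_resistance_from_adc,
    voltage_from_resistance,
)

CFG = DividerConfig()
NTC = ThermistorModel()


class TestDivider:
    @pytest.mark.parametrize(
        "adc, volts",
        [(4095, 5.0), (0, 0.0), (819, 1.0), (2047.5, 2.5)],
    )
    def test_adc_to_voltage_linear(self, adc, volts):
        assert adc_to_voltage(adc, CFG) == pytest.approx(volts)

    @pytest.mark.parametrize("adc", [-1, 4096])
    def test_adc_out_of_range_rejected(self, adc):
        with pytest.raises(ValueError, match="outside"):
            adc_to_voltage(adc, CFG)

    @pytest.mark.parametrize(
        "vout, ohms",
        [(2.5, 10_000.0), (1.0, 40_000.0), (5.0, 0.0)],
    )
    def test_resistance_from_voltage(self, vout, ohms):
        assert resistance_from_voltage(vout, CFG) == pytest.approx(ohms)

    def test_zero_voltage_is_open_circuit(self):
        with pytest.raises(OpenCircuitError):
            resistance_from_voltage(0.0, CFG)

    def test_over_supply_voltage_rejected(self):
        with pytest.raises(ValueError, match="supply"):
            resistance_from_voltage(5.01, CFG)

    @given(st.floats(min_value=1.0, max_value=1e7))
    @settings(max_examples=200, deadline=None)
    def test_divider_inversion_round_trip(self, r):
        """resistance_from_voltage exactly inverts the forward divider."""
        v = voltage_from_resistance(r, CFG)
        assert resistance_from_voltage(v, CFG) == pytest.approx(r, rel=1e-9)

    def test_nonstandard_config(self):
        cfg = DividerConfig(vcc=3.3, r_ext=4_700.0, adc_bits=10)
        assert cfg.adc_max == 1023
        assert adc_to_voltage(1023, cfg) == pytest.approx(3.3)
        assert resistance_from_voltage(1.65, cfg) == pytest.approx(4_700.0)

    @pytest.mark.parametrize("kwargs", [{"vcc": 0}, {"r_ext": -1}, {"adc_bits": 0}])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DividerConfig(**kwargs)


class TestThermistorChain:
    @pytest.mark.parametrize(
        "adc, ohms",
        [
            (819, 40_000.0),
            (4095, 0.0),
            (2048, (40_950_000 - 10_000 * 2048) / 2048),
        ],
    )
    def test_resistance_from_adc_closed_form(self, adc, ohms):
        assert thermistor_resistance_from_adc(adc, CFG) == pytest.approx(ohms)

    def test_zero_count_is_open_circuit(self):
        with pytest.raises(OpenCircuitError):
            thermistor_resistance_from_adc(0, CFG)

    def test_model_anchor_at_zero_celsius(self):
        with pytest.warns(UserWarning, match="working range"):
            assert temperature_from_resistance(24_710.0, NTC) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_inverse_of_printed_log_form(self):
        # independent evaluation of (ln 10000 - ln 24710) / (-0.036)
        expected = (math.log(10_000) - math.log(24_710)) / (-0.036)
        assert temperature_from_resistance(10_000.0, NTC) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(25.13, abs=0.005)

    def test_round_trip_identity_over_working_range(self):
        t = np.linspace(20.0, 50.0, 301)
        recovered = temperature_from_resistance(NTC.resistance_at(t), NTC)
        np.testing.assert_allclose(recovered, t, atol=1e-9)

    def test_direct_formula_matches_two_step_composition(self):
        """The single closed form and the R-then-T path agree everywhere."""
        adc = np.linspace(1.0, 4094.0, 1000)
        direct = temperature_from_adc(adc, CFG, NTC)
        composed = temperature_from_resistance(
            thermistor_resistance_from_adc(adc, CFG), NTC
        )
        np.testing.assert_allclose(direct, composed, atol=1e-9)

    def test_full_scale_count_has_no_temperature(self):
        with pytest.raises(ValueError, match="full-scale"):
            temperature_from_adc(4095, CFG, NTC)

    def test_count_at_model_anchor_reads_zero_celsius(self):
        adc = 40_950_000 / (10_000 + 24_710)
        with pytest.warns(UserWarning, match="working range"):
            assert temperature_from_adc(adc, CFG, NTC) == pytest.approx(
                0.0, abs=1e-9
            )


class TestExponentialFit:
    def test_exact_recovery_on_noiseless_curve(self):
        t = np.arange(20.0, 51.0, 5.0)
        pairs = list(zip(t, NTC.resistance_at(t)))
        fit = fit_exponential_calibration(pairs)
        assert isinstance(fit, CalibrationFit)
        assert fit.model.a == pytest.approx(NTC.a, rel=1e-9)
        assert fit.model.b == pytest.approx(NTC.b, rel=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        pairs = [(20.0, 12_000.0), (40.0, 6_000.0)]
        fit = fit_exponential_calibration(pairs)
        for t, r in pairs:
            assert fit.model.resistance_at(t) == pytest.approx(r, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rate_recovered_under_two_percent_noise(self, seed):
        rng = np.random.default_rng(seed)
        t = np.arange(20.0, 51.0)  # n = 31
        r = NTC.resistance_at(t) * (1 + 0.02 * rng.standard_normal(t.size))
        fit = fit_exponential_calibration(list(zip(t, r)))
        assert abs(fit.model.b - NTC.b) / abs(NTC.b) < 0.05

    @pytest.mark.parametrize(
        "pairs",
        [
            [(25.0, 10_000.0)],
            [(25.0, 10_000.0), (25.0, 9_000.0)],
            [(20.0, 10_000.0), (30.0, -5.0)],
        ],
    )
    def test_degenerate_inputs_rejected(self, pairs):
        with pytest.raises(ValueError):
            fit_exponential_calibration(pairs)


class TestForcePressureMass:
    def test_fsr402_active_area(self):
        assert active_area(6.35) == pytest.approx(126.68, abs=0.005)
        assert active_area(0.0) == 0.0
        assert active_area(1.0) == pytest.approx(math.pi)
        assert SensorGeometry().area_mm2 == pytest.approx(126.68, abs=0.005)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            active_area(-1.0)

    def test_plantar_pressure_range_to_force(self):
        low = force_from_pressure(80_000.0, 126.677)
        high = force_from_pressure(600_000.0, 126.677)
        assert round(low) == 10
        assert round(high) == 76
        assert low == pytest.approx(10.134, abs=0.001)
        assert high == pytest.approx(76.006, abs=0.001)

    def test_force_to_mass_range(self):
        assert round(mass_from_force(10.13416), 2) == 1.03
        assert round(mass_from_force(76.0062), 2) == 7.75
        assert mass_from_force(0.0) == 0.0

    @given(st.floats(min_value=0, max_value=1e6), st.floats(min_value=0, max_value=10))
    @settings(max_examples=100, deadline=None)
    def test_force_scales_linearly_in_pressure(self, p, k):
        assert force_from_pressure(k * p, 126.677) == pytest.approx(
            k * force_from_pressure(p, 126.677), rel=1e-9, abs=1e-12
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            force_from_pressure(-1.0, 10.0)
        with pytest.raises(ValueError):
            mass_from_force(10.0, g=0.0)


class TestFSRForceModel:
    def test_datasheet_anchor_point(self):
        # 100 g load (0.981 N under g = 9.81) at 10 kOhm
        assert force_from_resistance(10_000.0, FSRForceModel()) == pytest.approx(
            0.981
        )

    def test_anchor_nodes_exact(self):
        model = FSRForceModel()
        for r, f in model.anchors:
            assert force_from_resistance(r, model) == pytest.approx(f, rel=1e-12)

    def test_unloaded_sensor_reads_zero(self):
        model = FSRForceModel()
        assert force_from_resistance(1e9, model) == 0.0
        assert force_from_resistance(model.max_resistance * 1.01, model) == 0.0

    @given(
        st.floats(min_value=10.0, max_value=1e6),
        st.floats(min_value=10.0, max_value=1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_nonincreasing_in_resistance(self, r1, r2):
        lo, hi = sorted((r1, r2))
        model = FSRForceModel()
        assert force_from_resistance(lo, model) >= force_from_resistance(hi, model)

    @given(st.floats(min_value=0.2, max_value=90.0))
    @settings(max_examples=100, deadline=None)
    def test_force_resistance_round_trip(self, f):
        model = FSRForceModel()
        r = resistance_from_force(f, model)
        assert force_from_resistance(r, model) == pytest.approx(f, rel=1e-6)

    def test_zero_force_is_open_circuit(self):
        assert resistance_from_force(0.0) == math.inf

    @pytest.mark.parametrize(
        "anchors",
        [
            ((10_000.0, 1.0),),  # too few
            ((10_000.0, 1.0), (20_000.0, 2.0)),  # resistance rising with force
            ((10_000.0, -1.0), (5_000.0, 2.0)),  # negative force
        ],
    )
    def test_invalid_anchor_tables_rejected(self, anchors):
        with pytest.raises(ValueError):
            FSRForceModel(anchors=anchors)
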