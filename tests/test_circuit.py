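"""Single-diode device model, load line, operating point and thresholds."""

import numpy as np
import pytest

from plasmopv import circuit

# printed performance triples (J_sc A/m^2, V_oc V, FF, P_in W/m^2)
TRIPLES = [
    (9.5, 0.67, 0.785, 330.0), (7.5, 0.67, 0.755, 260.0),
    (23.0, 0.68, 0.78, 330.0), (19.0, 0.68, 0.775, 260.0),
    (25.0, 0.68, 0.765, 330.0), (25.0, 0.68, 0.765, 260.0),
    (30.0, 0.685, 0.78, 330.0), (32.0, 0.685, 0.752, 260.0),
    (35.0, 0.69, 0.765, 330.0), (38.0, 0.69, 0.80, 260.0),
]


class TestCalibration:
    @pytest.mark.parametrize("jsc,voc,ff,p_in", TRIPLES)
    def test_round_trip_all_printed_triples(self, jsc, voc, ff, p_in):
        """Recomputed V_oc within 5 mV and FF within 1 point."""
        params = circuit.calibrate_diode(jsc, voc, ff)
        curve = circuit.iv_curve(params, jsc, p_in)
        assert curve.voc == pytest.approx(voc, abs=5e-3)
        assert curve.ff == pytest.approx(ff, abs=0.01)

    def test_boundary_conditions(self):
        params = circuit.calibrate_diode(38.0, 0.69, 0.80)
        curve = circuit.iv_curve(params, 38.0, 260.0)
        assert curve.j_at(0.0) == pytest.approx(38.0, rel=1e-12)
        assert abs(curve.j_at(curve.voc)) <= 1e-6 * 38.0

    def test_infeasible_fill_factor_reports_range(self):
        with pytest.raises(ValueError, match="achievable"):
            circuit.calibrate_diode(38.0, 0.69, 0.99)

    def test_deterministic(self):
        a = circuit.calibrate_diode(32.0, 0.685, 0.752)
        b = circuit.calibrate_diode(32.0, 0.685, 0.752)
        assert a == b


class TestIVCurve:
    def test_pce_identity(self):
        params = circuit.calibrate_diode(38.0, 0.69, 0.80)
        curve = circuit.iv_curve(params, 38.0, 260.0)
        assert curve.pce * 260.0 == pytest.approx(curve.pmax_w_m2, rel=1e-9)
        assert curve.pmax_w_m2 == pytest.approx(
            curve.ff * curve.jsc * curve.voc, rel=1e-9)

    def test_monotone_nonincreasing(self):
        params = circuit.calibrate_diode(25.0, 0.68, 0.765)
        curve = circuit.iv_curve(params, 25.0, 260.0)
        assert np.all(np.diff(curve.current_density_a_m2) <= 0)

    def test_dark_device_is_flat(self):
        params = circuit.calibrate_diode(25.0, 0.68, 0.765)
        curve = circuit.iv_curve(params, 0.0, 260.0)
        assert curve.pmax_w_m2 == 0.0 and curve.voc == 0.0

    def test_preferred_configuration_power(self):
        """P_max ~ 21 W/m^2 for the top Table row; PCE ~ 8%."""
        params = circuit.calibrate_diode(38.0, 0.69, 0.80)
        curve = circuit.iv_curve(params, 38.0, 260.0)
        assert curve.pmax_w_m2 == pytest.approx(21.0, abs=1.0)
        assert curve.pce == pytest.approx(0.08, abs=0.005)


class TestLoadLine:
    def test_hand_value(self):
        line = circuit.load_line(4.3e-3)
        assert line(0.108) == pytest.approx(25.1, abs=0.05)
        assert line(0.0) == 0.0

    def test_impedance_scaling(self):
        assert circuit.load_line(8.6e-3)(0.2) == pytest.approx(
            circuit.load_line(4.3e-3)(0.2) / 2.0)

    def test_nonpositive_impedance_rejected(self):
        with pytest.raises(ValueError):
            circuit.load_line(0.0)


class TestOperatingPoint:
    def _curve(self, jsc=25.0, voc=0.68, ff=0.765, p_in=260.0):
        return circuit.iv_curve(circuit.calibrate_diode(jsc, voc, ff),
                                jsc, p_in)

    def test_point_lies_on_both_curves(self):
        curve = self._curve()
        op = circuit.operating_point(curve, 4.3e-3, 25.1)
        assert op.current_density_a_m2 == pytest.approx(
            op.voltage_v / 4.3e-3, rel=1e-9)
        assert curve.j_at(op.voltage_v) == pytest.approx(
            op.current_density_a_m2, rel=1e-9)

    def test_plateau_regime(self):
        """Jsc*Z far below the knee: J ~ Jsc and V ~ Jsc*Z."""
        curve = self._curve()
        op = circuit.operating_point(curve, 4.3e-3, 25.1)
        assert op.current_density_a_m2 == pytest.approx(25.0, rel=2e-3)
        assert op.voltage_v == pytest.approx(25.0 * 4.3e-3, rel=2e-3)

    def test_large_impedance_approaches_open_circuit(self):
        curve = self._curve()
        op = circuit.operating_point(curve, 1e3, 1.0)
        assert op.voltage_v == pytest.approx(curve.voc, rel=1e-3)
        assert not op.stimulates

    def test_stimulation_flag(self):
        curve = self._curve(jsc=40.0, voc=0.69, ff=0.80)
        assert circuit.operating_point(curve, 4.3e-3, 25.1).stimulates
        weak = self._curve(jsc=7.5, voc=0.67, ff=0.755)
        assert not circuit.operating_point(weak, 4.3e-3, 25.1).stimulates


class TestWaterWindowAndImpedance:
    @pytest.mark.parametrize("v,ok", [(0.69, True), (-0.11, True),
                                      (1.5, False), (-1.3, False)])
    def test_water_window(self, v, ok):
        assert circuit.water_window_check(v) is ok

    def test_threshold_pair_impedance(self):
        z = circuit.interface_impedance(-0.11, 25.1)
        assert z == pytest.approx(4.38e-3, abs=5e-5)  # 4.38 kOhm mm^2

    def test_impedance_trivials(self):
        assert circuit.interface_impedance(-1.0, 1.0) == 1.0
        assert circuit.interface_impedance(-2.0, 1.0) == 2.0


class TestThresholdIntensity:
    def test_threshold_scales_with_current_threshold_in_plateau(self):
        t1 = circuit.threshold_intensity(25.0, 0.26, 0.68, 0.765,
                                         4.3e-3, 12.55)
        t2 = circuit.threshold_intensity(25.0, 0.26, 0.68, 0.765,
                                         4.3e-3, 25.1)
        assert t2 == pytest.approx(2.0 * t1, rel=0.05)

    def test_zero_threshold_returns_floor(self):
        t = circuit.threshold_intensity(25.0, 0.26, 0.68, 0.765, 4.3e-3, 0.0)
        assert t == 0.005

    def test_unreachable_threshold_raises(self):
        with pytest.raises(ValueError, match="cap"):
            circuit.threshold_intensity(25.0, 0.26, 0.68, 0.765,
                                        4.3e-3, 1e4)
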