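"""Single-diode electrical model of the photovoltaic pixel.

The pixel's printed performance triples (J_sc, V_oc, FF) vary too little in
V_oc across a five-fold J_sc range for any single fixed-parameter diode, so
the diode is calibrated per configuration: the ideality factor is fitted so
the ideal single-diode curve

    J(V) = J_sc - J_0 (exp(V / (n V_T)) - 1)

reproduces the configuration's fill factor, and J_0 is pinned by V_oc.
Series resistance is zero and shunt resistance infinite by default; both
fields exist for sensitivity studies.  All quantities are photovoltaic-
quadrant magnitudes; the cathodic (negative) polarity of the stimulation
boundary is applied only when handing the operating point to the neuron
model.

The electrode-electrolyte interface is a resistive load line J = V / Z
through the origin; the device operating point is the intersection of the
two curves, and stimulation succeeds when its current density reaches the
activation threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from . import units

BOLTZMANN_J_K = 1.380649e-23


@dataclass(frozen=True)
class DiodeParams:
    j0_a_m2: float
    ideality: float
    r_series_ohm_m2: float = 0.0
    r_shunt_ohm_m2: float = np.inf
    temperature_k: float = 300.0

    def __post_init__(self) -> None:
        if self.j0_a_m2 <= 0 or self.ideality <= 0:
            raise ValueError("j0 and ideality must be positive")
        if self.r_series_ohm_m2 < 0 or self.r_shunt_ohm_m2 <= 0:
            raise ValueError("r_series >= 0 and r_shunt > 0 required")

    @property
    def thermal_voltage(self) -> float:
        return BOLTZMANN_J_K * self.temperature_k / units.ELEMENTARY_CHARGE_C


@dataclass(frozen=True)
class IVCurve:
    voltages_v: np.ndarray
    current_density_a_m2: np.ndarray
    jsc: float
    voc: float
    ff: float
    pmax_w_m2: float
    pce: float
    params: DiodeParams

    def j_at(self, voltage_v: float) -> float:
        return _diode_current(self.params, self.jsc, voltage_v)

    def to_csv(self, path) -> None:
        power = self.voltages_v * self.current_density_a_m2
        np.savetxt(path,
                   np.column_stack([self.voltages_v,
                                    self.current_density_a_m2, power]),
                   delimiter=",", comments="",
                   header="voltage_v,current_density_a_m2,power_w_m2",
                   fmt="%.8g")


@dataclass(frozen=True)
class OperatingPoint:
    voltage_v: float
    current_density_a_m2: float
    stimulates: bool


def _diode_current(params: DiodeParams, jsc: float, v: float) -> float:
    nvt = params.ideality * params.thermal_voltage
    j = jsc - params.j0_a_m2 * np.expm1(v / nvt)
    if np.isfinite(params.r_shunt_ohm_m2):
        j = j - v / params.r_shunt_ohm_m2
    return float(j)


def _ff_of_ideality(ideality: float, jsc: float, voc: float,
                    temperature_k: float = 300.0) -> float:
    """Fill factor of the ideal single-diode curve with J0 pinned by Voc."""
    vt = BOLTZMANN_J_K * temperature_k / units.ELEMENTARY_CHARGE_C
    nvt = ideality * vt
    j0 = jsc / np.expm1(voc / nvt)
    neg_power = lambda v: -(v * (jsc - j0 * np.expm1(v / nvt)))
    res = minimize_scalar(neg_power, bounds=(0.0, voc), method="bounded",
                          options={"xatol": 1e-9})
    return float(-res.fun / (jsc * voc))


def calibrate_diode(jsc: float, voc: float, ff: float,
                    temperature_k: float = 300.0) -> DiodeParams:
    """Fit the ideality factor (and J0) to a (J_sc, V_oc, FF) triple.

    Deterministic: bisection on the ideality over [0.5, 6], where the fill
    factor is strictly decreasing.
    """
    if not (0.0 < ff < 1.0) or voc <= 0 or jsc <= 0:
        raise ValueError("need jsc > 0, voc > 0 and 0 < ff < 1")
    lo, hi = 0.5, 6.0
    ff_hi = _ff_of_ideality(lo, jsc, voc, temperature_k)
    ff_lo = _ff_of_ideality(hi, jsc, voc, temperature_k)
    if not (ff_lo <= ff <= ff_hi):
        raise ValueError(
            f"fill factor {ff:.3f} unreachable by an ideal single diode with "
            f"Voc = {voc} V; achievable range [{ff_lo:.3f}, {ff_hi:.3f}]"
        )
    n = brentq(lambda x: _ff_of_ideality(x, jsc, voc, temperature_k) - ff,
               lo, hi, xtol=1e-10)
    vt = BOLTZMANN_J_K * temperature_k / units.ELEMENTARY_CHARGE_C
    j0 = jsc / np.expm1(voc / (n * vt))
    return DiodeParams(j0_a_m2=float(j0), ideality=float(n),
                       temperature_k=temperature_k)


def iv_curve(params: DiodeParams, jsc: float, p_in_w_m2: float,
             step_v: float = 1e-3) -> IVCurve:
    """Full current-voltage curve plus derived scalars.

    Voltage grid: ``step_v`` steps from 0 to 1.1 * V_oc; P_max is the grid
    maximum refined by a bounded scalar optimization around it.
    """
    if p_in_w_m2 <= 0:
        raise ValueError("incident power density must be positive")
    if jsc <= 0:
        v = np.arange(0.0, 0.5, step_v)
        zeros = np.zeros_like(v)
        return IVCurve(v, zeros, 0.0, 0.0, 0.0, 0.0, 0.0, params)
    nvt = params.ideality * params.thermal_voltage
    voc = nvt * np.log1p(jsc / params.j0_a_m2)
    v = np.arange(0.0, 1.1 * voc + 0.5 * step_v, step_v)
    j = np.array([_diode_current(params, jsc, vi) for vi in v])
    power = v * j
    i_max = int(np.argmax(power))
    lo = v[max(i_max - 1, 0)]
    hi = v[min(i_max + 1, len(v) - 1)]
    res = minimize_scalar(lambda x: -x * _diode_current(params, jsc, x),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    pmax = float(-res.fun)
    ff = pmax / (jsc * voc)
    return IVCurve(v, j, float(jsc), float(voc), float(ff), pmax,
                   pmax / p_in_w_m2, params)


def load_line(z_interface_ohm_m2: float):
    """Resistive electrode-interface line J(V) = V / Z through the origin."""
    if z_interface_ohm_m2 <= 0:
        raise ValueError("interface impedance must be positive")
    return lambda v: v / z_interface_ohm_m2


def operating_point(curve: IVCurve, z_interface_ohm_m2: float,
                    j_threshold_a_m2: float) -> OperatingPoint:
    """Intersection of the device curve and the electrode load line."""
    line = load_line(z_interface_ohm_m2)
    f = lambda v: curve.j_at(v) - line(v)
    if curve.jsc <= 0 or f(0.0) <= 0 or f(curve.voc) >= 0:
        raise ValueError("device curve and load line do not intersect "
                         "inside (0, Voc)")
    v_star = brentq(f, 0.0, curve.voc, xtol=1e-12, rtol=1e-15)
    j_star = line(v_star)
    return OperatingPoint(float(v_star), float(j_star),
                          bool(j_star >= j_threshold_a_m2))


def water_window_check(voltage_v: float) -> bool:
    """True iff |V| stays inside the +-1.23 V electrolysis-free window."""
    return abs(voltage_v) < units.WATER_WINDOW_V


def interface_impedance(v_threshold_v: float, j_threshold_a_m2: float
                        ) -> float:
    """Z = |V| / J from a threshold voltage/current-density pair (Ohm m^2)."""
    if j_threshold_a_m2 <= 0:
        raise ValueError("threshold current density must be positive")
    return abs(v_threshold_v) / j_threshold_a_m2


def threshold_intensity(jsc_at_ref: float, ref_intensity_mw_mm2: float,
                        voc: float, ff: float,
                        z_interface_ohm_m2: float, j_threshold_a_m2: float,
                        resolution_mw_mm2: float = 0.005,
                        intensity_cap_mw_mm2: float = 5.0) -> float:
    """Minimum incident intensity whose operating point stimulates.

    J_sc is linear in intensity; (V_oc, FF) of the calibrated device are held
    at their reference-configuration values while the intensity is bisected
    to the requested resolution.
    """
    params = calibrate_diode(jsc_at_ref, voc, ff)

    def stimulates(intensity: float) -> bool:
        if intensity <= 0:
            return j_threshold_a_m2 <= 0
        jsc = jsc_at_ref * intensity / ref_intensity_mw_mm2
        curve = iv_curve(params, jsc, units.intensity_mw_mm2_to_w_m2(intensity))
        try:
            op = operating_point(curve, z_interface_ohm_m2, j_threshold_a_m2)
        except ValueError:
            return False
        return op.stimulates

    if j_threshold_a_m2 <= 0:
        return resolution_mw_mm2
    if not stimulates(intensity_cap_mw_mm2):
        raise ValueError(
            f"activation threshold not reachable below the "
            f"{intensity_cap_mw_mm2} mW/mm^2 intensity cap"
        )
    lo, hi = 0.0, intensity_cap_mw_mm2
    while hi - lo > 0.25 * resolution_mw_mm2:
        mid = 0.5 * (lo + hi)
        if stimulates(mid):
            hi = mid
        else:
            lo = mid
    return round(hi / resolution_mw_mm2) * resolution_mw_mm2
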