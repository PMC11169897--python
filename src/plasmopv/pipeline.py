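"""End-to-end scenario runs: optics -> attenuation -> J_sc -> I-V ->
operating point -> stimulation verdict, plus the multi-scenario
performance table.

The device stage needs an (V_oc, FF) pair, which the lumped diode cannot
predict from optics alone; those come from the packaged performance
reference for the matching configuration, while J_sc is always the
pipeline's own computed value.  Every calibrated constant used along the
way is echoed in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import circuit, photocurrent, units
from .attenuation import AttenuationResult, total_transmittance
from .materials import DeviceScenario, load_calibration
from .quasistatic import ParticleSpec, cross_sections, default_grid, find_lspr

# electrode-electrolyte areal impedance from the threshold pair
# (|-0.11 V| / 25.1 A/m^2) and the activation current density
DEFAULT_Z_OHM_M2 = circuit.interface_impedance(-0.11, 25.1)
DEFAULT_J_THRESHOLD_A_M2 = 25.1


def load_performance_reference() -> pd.DataFrame:
    p = resources.files("plasmopv.data").joinpath("performance_reference.csv")
    with resources.as_file(p) as path:
        return pd.read_csv(path)


def reference_performance(scenario: DeviceScenario) -> dict:
    """Printed (J_sc, V_oc, FF, PCE) for the matching configuration."""
    df = load_performance_reference()
    bare = scenario.fill_fraction == 0.0
    mask = ((df["wavelength_nm"] == scenario.wavelength_nm)
            & (np.isclose(df["intensity_mW_mm2"], scenario.intensity_mW_mm2)))
    if bare:
        mask &= df["a_radius_nm"].isna()
    else:
        mask &= (np.isclose(df["a_radius_nm"], scenario.a_radius_nm)
                 & np.isclose(df["fill_fraction"], scenario.fill_fraction))
    rows = df[mask]
    if len(rows) != 1:
        raise LookupError(
            "no packaged performance reference for this configuration "
            f"(wavelength {scenario.wavelength_nm} nm, r "
            f"{scenario.a_radius_nm} nm, f_s {scenario.fill_fraction}, "
            f"{scenario.intensity_mW_mm2} mW/mm^2); tabulated rows cover the "
            "study grid only"
        )
    row = rows.iloc[0]
    return {"jsc_a_m2": float(row["jsc_a_m2"]), "voc_v": float(row["voc_v"]),
            "ff": float(row["ff_pct"]) / 100.0,
            "pce": float(row["pce_pct"]) / 100.0}


@dataclass(frozen=True)
class PipelineReport:
    scenario: DeviceScenario
    lspr_nm: float | None
    peak_q_abs: float | None
    peak_q_scat: float | None
    attenuation: AttenuationResult
    jsc: photocurrent.JscBreakdown
    voc_v: float
    ff: float
    pmax_w_m2: float
    pce: float
    operating_voltage_v: float
    operating_current_a_m2: float
    stimulates: bool
    voc_in_water_window: bool
    operating_point_in_water_window: bool
    z_interface_ohm_m2: float
    j_threshold_a_m2: float
    calibration: dict

    def to_text(self) -> str:
        s = self.scenario
        lines = [
            "scenario:",
            f"  a_radius_nm={s.a_radius_nm} fill_fraction={s.fill_fraction} "
            f"k_gap_nm={s.k_gap_nm} wavelength_nm={s.wavelength_nm} "
            f"intensity_mW_mm2={s.intensity_mW_mm2} "
            f"include_k_term={s.include_k_term}",
            "single-particle optics:",
            f"  lspr_nm={self.lspr_nm} peak_q_abs={self.peak_q_abs} "
            f"peak_q_scat={self.peak_q_scat}",
            "attenuation:",
            f"  t_np={self.attenuation.t_nanoparticles:.6g} "
            f"t_layer={self.attenuation.t_layer:.6g} "
            f"t_total={self.attenuation.t_total:.6g}",
            "photocurrent (A/m^2):",
            f"  jsc_total={self.jsc.jsc_total:.6g} "
            f"bare={self.jsc.term_bare:.6g} a_np={self.jsc.term_a_np:.6g} "
            f"k_np={self.jsc.term_k_np:.6g}",
            f"  v1={self.jsc.v1:.6g} v2={self.jsc.v2:.6g} "
            f"k_coeff={self.jsc.k_coeff:.6g} q_sc={self.jsc.q_sc:.6g}",
            "device:",
            f"  voc_v={self.voc_v:.6g} ff={self.ff:.6g} "
            f"pmax_w_m2={self.pmax_w_m2:.6g} pce={self.pce:.6g}",
            "operating point:",
            f"  v={self.operating_voltage_v:.6g} V "
            f"j={self.operating_current_a_m2:.6g} A/m^2 "
            f"(load line Z={self.z_interface_ohm_m2:.6g} Ohm m^2)",
            f"  stimulates={self.stimulates} "
            f"(threshold {self.j_threshold_a_m2} A/m^2)",
            "water window:",
            f"  voc={self.voc_in_water_window} "
            f"operating_point={self.operating_point_in_water_window}",
            "calibration constants:",
        ]
        for key in ("collection_efficiency", "layer_effective_path_nm",
                    "np_channel_path_cm", "kappa_a", "kappa_k"):
            lines.append(f"  {key}={self.calibration[key]:.10g}")
        return "\n".join(lines) + "\n"


def run_scenario(scenario: DeviceScenario | str | Path,
                 z_interface_ohm_m2: float = DEFAULT_Z_OHM_M2,
                 j_threshold_a_m2: float = DEFAULT_J_THRESHOLD_A_M2
                 ) -> PipelineReport:
    """Run the full chain for one scenario (object or YAML path)."""
    if not isinstance(scenario, DeviceScenario):
        scenario = DeviceScenario.from_yaml(scenario)
    calib = load_calibration()

    if scenario.fill_fraction > 0:
        p = ParticleSpec(radius_nm=scenario.a_radius_nm)
        spec = cross_sections(p, default_grid())
        lspr = find_lspr(p)
        peak_q_abs = float(np.max(spec.q_abs))
        peak_q_scat = float(np.max(spec.q_scat))
    else:
        lspr = peak_q_abs = peak_q_scat = None

    att = total_transmittance(scenario, calib)
    jsc = photocurrent.jsc_composite(scenario, calib)

    ref = reference_performance(scenario)
    params = circuit.calibrate_diode(ref["jsc_a_m2"], ref["voc_v"], ref["ff"])
    p_in = units.intensity_mw_mm2_to_w_m2(scenario.intensity_mW_mm2)
    curve = circuit.iv_curve(params, jsc.jsc_total, p_in)
    op = circuit.operating_point(curve, z_interface_ohm_m2, j_threshold_a_m2)

    return PipelineReport(
        scenario=scenario,
        lspr_nm=lspr,
        peak_q_abs=peak_q_abs,
        peak_q_scat=peak_q_scat,
        attenuation=att,
        jsc=jsc,
        voc_v=curve.voc,
        ff=curve.ff,
        pmax_w_m2=curve.pmax_w_m2,
        pce=curve.pce,
        operating_voltage_v=op.voltage_v,
        operating_current_a_m2=op.current_density_a_m2,
        stimulates=op.stimulates,
        voc_in_water_window=circuit.water_window_check(curve.voc),
        operating_point_in_water_window=circuit.water_window_check(
            op.voltage_v),
        z_interface_ohm_m2=z_interface_ohm_m2,
        j_threshold_a_m2=j_threshold_a_m2,
        calibration=calib,
    )


def compare_table(scenarios) -> pd.DataFrame:
    """One performance row per scenario (I_in, J_sc, V_oc, FF, PCE)."""
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("need at least one scenario")
    rows = []
    for scn in scenarios:
        rep = run_scenario(scn)
        rows.append({
            "wavelength_nm": scn.wavelength_nm,
            "a_radius_nm": scn.a_radius_nm if scn.fill_fraction else np.nan,
            "fill_fraction": scn.fill_fraction,
            "with_k": scn.include_k_term,
            "intensity_mW_mm2": scn.intensity_mW_mm2,
            "jsc_a_m2": rep.jsc.jsc_total,
            "voc_v": rep.voc_v,
            "ff_pct": rep.ff * 100.0,
            "pce_pct": rep.pce * 100.0,
        })
    return pd.DataFrame(rows)


def study_scenarios() -> list[DeviceScenario]:
    """The configurations of the printed performance table."""
    from .materials import bare_scenario
    out = [
        bare_scenario(453.0, 0.33), bare_scenario(453.0, 0.26),
        bare_scenario(250.0, 0.33), bare_scenario(250.0, 0.26),
    ]
    for f_s in (0.05, 0.075, 0.10):
        out.append(DeviceScenario(a_radius_nm=7.5, fill_fraction=f_s,
                                  intensity_mW_mm2=0.33))
        out.append(DeviceScenario(a_radius_nm=10.0, fill_fraction=f_s,
                                  intensity_mW_mm2=0.26))
    return out
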