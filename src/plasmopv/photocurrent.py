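"""Carrier generation and short-circuit current density.

Bare layer: the generation rate G = alpha * lambda * I0 * P / (h c) and
J_sc = G * q * L * eta, where P is the exciton dissociation probability and
eta a single calibrated carrier-collection efficiency (frozen in
calibration.json) that converts optical generation into collected current.

Composite device: a three-term balance

    J_sc = eta * I0 q L lambda/(h c) * [ 0.70 * alpha_1 * (1 - f_s - v1 f_s - v2)
           + 0.85 * kappa_A * alpha_2 * (1 - Q_sc) * v1 f_s
           + k * 0.85 * kappa_K * alpha_2 * v2 ]

where alpha_1 is the blend absorption coefficient, alpha_2 the silver one,
v1 = Q_abs^(3/2) the near-field influence volume of one A-AgNP relative to
its own volume, v2 the fraction of the active layer influenced by the
cathode particles' absorption, and k = T_r * A_b couples the light that
reaches and is absorbed by the cathode array back into generation.
kappa_A and kappa_K are dimensionless one-point calibration factors (the
prose model under-determines the absolute scale of the enhancement terms);
they are fitted once at the documented anchors and frozen, so the rest of
the (radius, f_s, intensity) grid is a genuine prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .attenuation import total_transmittance
from .karray import ArraySpec, ab_at, reference_spectra
from .materials import DeviceScenario, load_calibration, load_optical_constants
from .quasistatic import ParticleSpec, cross_sections, default_grid


@dataclass(frozen=True)
class JscBreakdown:
    """Three-term short-circuit current density audit record (A/m^2)."""

    wavelength_nm: float
    jsc_total: float
    term_bare: float
    term_a_np: float
    term_k_np: float
    v1: float
    v2: float
    k_coeff: float
    q_sc: float
    t_r: float
    a_b: float

    def as_report(self) -> str:
        return "\n".join(f"{k:16s} {v:.6g}" for k, v in vars(self).items())


def generation_rate(alpha_per_m: float, wavelength_nm: float,
                    intensity_w_m2: float, p_dissoc: float) -> float:
    """Free-carrier generation rate G = alpha*lambda*I0*P/(hc), m^-3 s^-1."""
    if min(alpha_per_m, wavelength_nm, intensity_w_m2) < 0:
        raise ValueError("alpha, wavelength and intensity must be >= 0")
    if not (0.0 < p_dissoc <= 1.0):
        raise ValueError("dissociation probability must lie in (0, 1]")
    lam_m = wavelength_nm * units.NM_TO_M
    return alpha_per_m * lam_m * intensity_w_m2 * p_dissoc / units.HC_J_M


def _alpha_per_m(material: str, wavelength_nm: float) -> float:
    table = load_optical_constants(material)
    _, k = table.nk_at(wavelength_nm)
    return float(4.0 * np.pi * k / (wavelength_nm * units.NM_TO_M))


def jsc_bare(scenario: DeviceScenario, calib: dict | None = None) -> float:
    """Bare-layer J_sc = G q L eta at the scenario wavelength/intensity."""
    calib = calib or load_calibration()
    alpha1 = _alpha_per_m("active_blend", scenario.wavelength_nm)
    g = generation_rate(
        alpha1, scenario.wavelength_nm,
        units.intensity_mw_mm2_to_w_m2(scenario.intensity_mW_mm2),
        scenario.p_bare,
    )
    return (g * units.ELEMENTARY_CHARGE_C * scenario.layer_L_nm * units.NM_TO_M
            * calib["collection_efficiency"])


def volume_ratio_v1(q_abs_peak: float) -> float:
    """v1 = Q_abs^(3/2): the sphere whose cross-sectional area equals C_abs,
    volumed against the particle itself."""
    if q_abs_peak <= 0:
        raise ValueError("peak Q_abs must be positive")
    return float(q_abs_peak ** 1.5)


def volume_ratio_v2(per_particle_c_abs_nm2: float,
                    scenario: DeviceScenario,
                    l_influence_nm: float | None = None) -> float:
    """Fraction of the active layer influenced by cathode-particle absorption.

    v2 = (areal density of K-AgNPs) * C_abs * L_influence / L, with the
    influence depth defaulting to the K-AgNP radius.
    """
    if per_particle_c_abs_nm2 < 0:
        raise ValueError("per-particle C_abs must be >= 0")
    array = ArraySpec(radius_nm=scenario.k_radius_nm, gap_nm=scenario.k_gap_nm)
    density_per_nm2 = 1.0 / array.unit_cell_area_nm2
    l_infl = scenario.k_radius_nm if l_influence_nm is None else l_influence_nm
    return float(density_per_nm2 * per_particle_c_abs_nm2 * l_infl
                 / scenario.layer_L_nm)


def _particle_optics(scenario: DeviceScenario) -> tuple[float, float]:
    """(peak Q_abs, Q_sc at the scenario wavelength) for the A-AgNPs."""
    p = ParticleSpec(radius_nm=scenario.a_radius_nm)
    spec = cross_sections(p, default_grid())
    q_abs_peak = float(np.max(spec.q_abs))
    i = int(np.argmin(np.abs(spec.wavelengths_nm - scenario.wavelength_nm)))
    return q_abs_peak, float(spec.q_sc[i])


def reference_c_abs_per_kagnp(scenario: DeviceScenario) -> float:
    """Per-particle cathode C_abs at the scenario wavelength (nm^2),
    from the packaged reference table."""
    spectra = reference_spectra(
        ArraySpec(radius_nm=scenario.k_radius_nm, gap_nm=scenario.k_gap_nm))
    match = np.isclose(spectra.wavelengths_nm, scenario.wavelength_nm,
                       atol=0.5)
    values = spectra.per_particle_c_abs_nm2[match]
    values = values[~np.isnan(values)]
    if len(values) == 0:
        raise ValueError(
            "no tabulated per-particle C_abs at "
            f"{scenario.wavelength_nm} nm for gap {scenario.k_gap_nm} nm"
        )
    return float(values[0])


def jsc_composite(scenario: DeviceScenario, calib: dict | None = None,
                  ab_mode: str = "reference_table") -> JscBreakdown:
    """Three-term composite J_sc for one scenario (A/m^2)."""
    calib = calib or load_calibration()
    lam = scenario.wavelength_nm
    intensity_w_m2 = units.intensity_mw_mm2_to_w_m2(scenario.intensity_mW_mm2)
    prefactor = (calib["collection_efficiency"] * intensity_w_m2
                 * units.ELEMENTARY_CHARGE_C
                 * scenario.layer_L_nm * units.NM_TO_M
                 * lam * units.NM_TO_M / units.HC_J_M)

    alpha1 = _alpha_per_m("active_blend", lam)
    alpha2 = _alpha_per_m("silver", lam)

    use_a = scenario.include_a_term and scenario.fill_fraction > 0
    if use_a:
        q_abs_peak, q_sc = _particle_optics(scenario)
        v1 = volume_ratio_v1(q_abs_peak)
    else:
        q_sc, v1 = 0.0, 0.0

    if scenario.include_k_term:
        c_abs_k = reference_c_abs_per_kagnp(scenario)
        v2 = volume_ratio_v2(c_abs_k, scenario)
        att = total_transmittance(scenario, calib)
        a_b = ab_at(ArraySpec(radius_nm=scenario.k_radius_nm,
                              gap_nm=scenario.k_gap_nm), lam, ab_mode)
        t_r = att.t_total
        k_coeff = t_r * a_b
    else:
        v2, t_r, a_b, k_coeff = 0.0, 0.0, 0.0, 0.0

    f_s = scenario.fill_fraction
    absorber_fraction = 1.0 - f_s - v1 * f_s - v2
    if absorber_fraction < 0:
        raise ValueError(
            f"negative bare-absorber fraction ({absorber_fraction:.3f}): "
            "f_s too large for the influence-volume conventions"
        )

    term_bare = prefactor * scenario.p_bare * alpha1 * absorber_fraction
    term_a = (prefactor * scenario.p_enhanced * calib["kappa_a"] * alpha2
              * (1.0 - q_sc) * v1 * f_s) if use_a else 0.0
    term_k = (prefactor * scenario.p_enhanced * calib["kappa_k"] * alpha2
              * k_coeff * v2) if scenario.include_k_term else 0.0

    return JscBreakdown(
        wavelength_nm=lam,
        jsc_total=term_bare + term_a + term_k,
        term_bare=term_bare,
        term_a_np=term_a,
        term_k_np=term_k,
        v1=v1,
        v2=v2,
        k_coeff=k_coeff,
        q_sc=q_sc,
        t_r=t_r,
        a_b=a_b,
    )
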