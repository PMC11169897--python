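"""Beer-Lambert attenuation through the A-AgNPs and the bare active layer.

Two independent channels multiply into the total transmittance T_r that
scales the light reaching the cathode array:

* nanoparticle channel, decadic: T_np = 10^(-eps*c*l) with the molar
  absorptivity eps = N_A * sigma / (2.3e3) (sigma in cm^2 per absorber),
  the A-AgNP molar number concentration c = f_s / (V_NP * N_A), and a
  calibrated path length l;
* host-layer channel, natural: T_layer = exp(-alpha * x * (1 - f_s)) with
  alpha = 4*pi*k/lambda from the blend fixture and a calibrated effective
  optical path x.  The (1 - f_s) factor is the volume displaced by the
  embedded particles: loading the layer with silver removes that much
  absorbing blend.

Both path lengths are calibration constants shipped with the package (see
calibration.json) because the geometric 70 nm thickness cannot reproduce
both channels' anchor transmittances simultaneously; the two calibrations
are kept independent and are reported in every audit record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import units
from .materials import DeviceScenario, load_calibration, load_optical_constants
from .quasistatic import ParticleSpec, cross_sections, default_grid


@dataclass(frozen=True)
class AttenuationResult:
    """Audit record of one total-transmittance evaluation."""

    t_nanoparticles: float
    t_layer: float
    t_total: float
    absorbance_np: float
    molar_absorptivity_l_mol_cm: float
    concentration_mol_l: float
    np_path_cm: float
    layer_alpha_per_m: float
    layer_path_nm: float

    def as_report(self) -> str:
        lines = [f"{k:32s} {v:.6g}" for k, v in vars(self).items()]
        return "\n".join(lines)


def molar_absorptivity(c_abs_cm2: float, atoms_per_np: float) -> float:
    """Molar absorptivity eps = N_A * sigma / (2.3e3), L mol^-1 cm^-1.

    ``sigma = c_abs / atoms_per_np`` is the per-absorber cross-section in
    cm^2; the 2.3e3 converts the natural-log cross-section into the decadic,
    per-mole, per-cm convention.
    """
    if atoms_per_np <= 0:
        raise ValueError("atoms_per_np must be positive")
    if c_abs_cm2 < 0:
        raise ValueError("absorption cross-section must be >= 0")
    sigma_cm2 = c_abs_cm2 / atoms_per_np
    return units.AVOGADRO_PER_MOL * sigma_cm2 / 2.3e3


def np_transmission(epsilon_l_mol_cm: float, concentration_mol_l: float,
                    path_cm: float) -> float:
    """Decadic Beer-Lambert transmission 10^(-eps*c*l)."""
    if min(epsilon_l_mol_cm, concentration_mol_l, path_cm) < 0:
        raise ValueError("Beer-Lambert inputs must be >= 0")
    return 10.0 ** (-(epsilon_l_mol_cm * concentration_mol_l * path_cm))


def layer_transmission(alpha_per_m: float, path_m: float) -> float:
    """Natural Beer-Lambert transmission exp(-alpha*x)."""
    if alpha_per_m < 0:
        raise ValueError("absorption coefficient must be >= 0")
    if path_m <= 0:
        raise ValueError("path length must be positive")
    return float(np.exp(-alpha_per_m * path_m))


def atoms_per_nanoparticle(radius_nm: float) -> float:
    """Silver atoms in one sphere, from the bulk atomic density."""
    volume_nm3 = 4.0 / 3.0 * np.pi * radius_nm**3
    return units.SILVER_ATOM_DENSITY_PER_NM3 * volume_nm3


def np_molar_concentration(fill_fraction: float, radius_nm: float) -> float:
    """Molar concentration (mol/L) of the absorbing silver *atoms*.

    The molar absorptivity is built from the per-atom cross-section
    sigma = C_abs / N, so the matching concentration is the atom molarity
    (f_s / V_NP particles per volume) * (N atoms per particle) / N_A.
    The particle count cancels: the optical depth scales with f_s and is
    independent of the particle radius, as it must be for a fixed silver
    volume loading.
    """
    if fill_fraction < 0:
        raise ValueError("fill_fraction must be >= 0")
    volume_nm3 = 4.0 / 3.0 * np.pi * radius_nm**3
    np_per_nm3 = fill_fraction / volume_nm3
    atoms_per_nm3 = np_per_nm3 * atoms_per_nanoparticle(radius_nm)
    per_litre = atoms_per_nm3 * 1e24  # 1 L = 1e24 nm^3
    return per_litre / units.AVOGADRO_PER_MOL


def blend_alpha_per_m(wavelength_nm: float) -> float:
    """Absorption coefficient of the blend, alpha = 4*pi*k/lambda (m^-1)."""
    blend = load_optical_constants("active_blend")
    _, k = blend.nk_at(wavelength_nm)
    return float(4.0 * np.pi * k / (wavelength_nm * units.NM_TO_M))


def peak_c_abs_nm2(radius_nm: float) -> float:
    """Resonance-peak absorption cross-section of an A-AgNP in the blend."""
    spec = cross_sections(ParticleSpec(radius_nm=radius_nm), default_grid())
    return float(np.max(spec.c_abs_nm2))


def c_abs_at_nm2(radius_nm: float, wavelength_nm: float) -> float:
    """A-AgNP absorption cross-section at one wavelength (nm^2)."""
    spec = cross_sections(ParticleSpec(radius_nm=radius_nm),
                          np.asarray([wavelength_nm]))
    return float(spec.c_abs_nm2[0])


def total_transmittance(scenario: DeviceScenario,
                        calib: dict | None = None) -> AttenuationResult:
    """Total transmittance T_r = T_np * T_layer for one scenario."""
    calib = calib or load_calibration()

    # nanoparticle channel
    if scenario.fill_fraction > 0:
        c_abs_nm2 = c_abs_at_nm2(scenario.a_radius_nm, scenario.wavelength_nm)
        eps = molar_absorptivity(c_abs_nm2 * units.NM2_TO_CM2,
                                 atoms_per_nanoparticle(scenario.a_radius_nm))
        conc = np_molar_concentration(scenario.fill_fraction,
                                      scenario.a_radius_nm)
        path_cm = calib["np_channel_path_cm"]
        t_np = np_transmission(eps, conc, path_cm)
        absorbance = eps * conc * path_cm
    else:
        eps, conc, path_cm, t_np, absorbance = 0.0, 0.0, 0.0, 1.0, 0.0

    # host-layer channel
    alpha = blend_alpha_per_m(scenario.wavelength_nm)
    x_eff_nm = calib["layer_effective_path_nm"]
    absorber_fraction = 1.0 - scenario.fill_fraction
    t_layer = layer_transmission(alpha,
                                 x_eff_nm * units.NM_TO_M * absorber_fraction)

    return AttenuationResult(
        t_nanoparticles=t_np,
        t_layer=t_layer,
        t_total=t_np * t_layer,
        absorbance_np=absorbance,
        molar_absorptivity_l_mol_cm=eps,
        concentration_mol_l=conc,
        np_path_cm=path_cm,
        layer_alpha_per_m=alpha,
        layer_path_nm=x_eff_nm,
    )
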