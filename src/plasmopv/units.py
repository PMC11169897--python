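"""Physical constants and the unit conventions used across the package.

Conventions (all conversions live here, nowhere else):

* wavelengths in nanometres (vacuum values unless stated otherwise),
* incident intensities in mW/mm^2 at the device interface
  (1 mW/mm^2 = 1000 W/m^2),
* current densities in A/m^2,
* single-particle cross-sections in nm^2,
* molar absorptivity in L mol^-1 cm^-1, concentrations in mol/L,
  Beer-Lambert path lengths in cm.
"""

# CODATA-level constants (SI)
PLANCK_J_S = 6.62607015e-34
SPEED_OF_LIGHT_M_S = 2.99792458e8
ELEMENTARY_CHARGE_C = 1.602176634e-19
AVOGADRO_PER_MOL = 6.02214076e23

HC_J_M = PLANCK_J_S * SPEED_OF_LIGHT_M_S

# Bulk silver: 10.49 g/cm^3 / 107.8682 g/mol -> atoms per nm^3
SILVER_ATOM_DENSITY_PER_NM3 = 10.49 / 107.8682 * AVOGADRO_PER_MOL * 1e-21

NM_TO_M = 1e-9
NM2_TO_CM2 = 1e-14
NM_TO_CM = 1e-7

# Electrochemical water window half-width used as the stimulation safety bound (V)
WATER_WINDOW_V = 1.23


def intensity_mw_mm2_to_w_m2(intensity_mw_mm2: float) -> float:
    """Incident intensity: mW/mm^2 -> W/m^2."""
    return intensity_mw_mm2 * 1000.0


def w_m2_to_intensity_mw_mm2(intensity_w_m2: float) -> float:
    return intensity_w_m2 / 1000.0


def photon_energy_j(wavelength_nm: float) -> float:
    """Photon energy at a vacuum wavelength (J)."""
    return HC_J_M / (wavelength_nm * NM_TO_M)


def ev_to_nm(energy_ev: float) -> float:
    return HC_J_M / (energy_ev * ELEMENTARY_CHARGE_C) / NM_TO_M


def nm_to_ev(wavelength_nm: float) -> float:
    return HC_J_M / (wavelength_nm * NM_TO_M) / ELEMENTARY_CHARGE_C
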