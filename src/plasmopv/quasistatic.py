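"""Quasi-static (dipole-limit) optics of a single metal nanosphere.

For a sphere much smaller than the wavelength the polarizability is

    alpha = 3 V (eps_m - eps_s) / (eps_m + 2 eps_s),

a volume-dimensioned quantity, and the cross-sections follow as

    C_abs  = (2 pi / lambda) * Im(alpha)
    C_scat = (1 / 6 pi) * (2 pi / lambda)^4 * |alpha|^2

with lambda the vacuum wavelength by default (``in_medium_wavelength=True``
switches both prefactors to lambda / n_s).  At the Froehlich condition
Re(eps_m + 2 eps_s) = 0 the polarizability is maximal: the localized surface
plasmon resonance.  Normalized efficiencies divide by the geometric
cross-section pi r^2; the scattering efficiency Q_sc = C_scat/(C_scat+C_abs)
measures how much of the removed light is re-radiated rather than absorbed.

No radiative (size) correction is applied here; the radiatively corrected
polarizability used for particle arrays lives in :mod:`plasmopv.karray`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import OpticalConstants, load_optical_constants

QUASISTATIC_MAX_RADIUS_NM = 50.0


@dataclass(frozen=True)
class ParticleSpec:
    """A metal nanosphere in a host medium, in the dipole-limit size range."""

    radius_nm: float
    metal: str = "silver"
    medium: str = "active_blend"

    def __post_init__(self) -> None:
        if not (0.0 < self.radius_nm <= QUASISTATIC_MAX_RADIUS_NM):
            raise ValueError(
                f"radius must lie in (0, {QUASISTATIC_MAX_RADIUS_NM:.0f}] nm "
                "for the quasi-static dipole limit"
            )

    @property
    def volume_nm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_nm**3

    def tables(self) -> tuple[OpticalConstants, OpticalConstants]:
        return (load_optical_constants(self.metal),
                load_optical_constants(self.medium))


@dataclass(frozen=True)
class CrossSectionSpectrum:
    """Absorption/scattering cross-sections and efficiencies on a grid."""

    wavelengths_nm: np.ndarray
    c_abs_nm2: np.ndarray
    c_scat_nm2: np.ndarray
    q_abs: np.ndarray
    q_scat: np.ndarray
    q_sc: np.ndarray

    def at(self, wavelength_nm: float) -> dict:
        i = int(np.argmin(np.abs(self.wavelengths_nm - wavelength_nm)))
        if abs(self.wavelengths_nm[i] - wavelength_nm) > 0.5:
            raise ValueError(
                f"wavelength {wavelength_nm} nm not on the computed grid"
            )
        return {
            "wavelength_nm": float(self.wavelengths_nm[i]),
            "c_abs_nm2": float(self.c_abs_nm2[i]),
            "c_scat_nm2": float(self.c_scat_nm2[i]),
            "q_abs": float(self.q_abs[i]),
            "q_scat": float(self.q_scat[i]),
            "q_sc": float(self.q_sc[i]),
        }

    def to_csv(self, path) -> None:
        data = np.column_stack([
            self.wavelengths_nm, self.c_abs_nm2, self.c_scat_nm2,
            self.q_abs, self.q_scat, self.q_sc,
        ])
        np.savetxt(
            path, data, delimiter=",", comments="",
            header="wavelength_nm,c_abs_nm2,c_scat_nm2,q_abs,q_scat,q_sc",
            fmt="%.10g",
        )


def polarizability(p: ParticleSpec, wavelength_nm,
                   metal_table: OpticalConstants | None = None,
                   medium_table: OpticalConstants | None = None):
    """Quasi-static dipole polarizability alpha (nm^3), complex."""
    metal = metal_table or load_optical_constants(p.metal)
    medium = medium_table or load_optical_constants(p.medium)
    eps_m = metal.permittivity(wavelength_nm)
    eps_s = medium.permittivity(wavelength_nm)
    return 3.0 * p.volume_nm3 * (eps_m - eps_s) / (eps_m + 2.0 * eps_s)


def cross_sections(p: ParticleSpec, wavelengths_nm,
                   in_medium_wavelength: bool = False,
                   metal_table: OpticalConstants | None = None,
                   medium_table: OpticalConstants | None = None
                   ) -> CrossSectionSpectrum:
    """Quasi-static absorption/scattering spectra of a single sphere.

    ``in_medium_wavelength=True`` evaluates the 2*pi/lambda prefactors at the
    in-medium wavelength lambda/n_s instead of the vacuum wavelength.
    Explicit tables override the packaged fixtures (used by calibration).
    """
    wl = np.atleast_1d(np.asarray(wavelengths_nm, dtype=float))
    if wl.size == 0:
        raise ValueError("empty wavelength grid")
    metal = metal_table or load_optical_constants(p.metal)
    medium = medium_table or load_optical_constants(p.medium)
    alpha = polarizability(p, wl, metal, medium)
    lam = wl
    if in_medium_wavelength:
        n_s, _ = medium.nk_at(wl)
        lam = wl / n_s
    wavenumber = 2.0 * np.pi / lam  # nm^-1
    c_abs = wavenumber * np.imag(alpha)
    c_scat = wavenumber**4 * np.abs(alpha) ** 2 / (6.0 * np.pi)
    geom = np.pi * p.radius_nm**2
    q_abs = c_abs / geom
    q_scat = c_scat / geom
    total = c_scat + c_abs
    q_sc = np.divide(c_scat, total, out=np.zeros_like(c_scat),
                     where=total > 0)
    return CrossSectionSpectrum(wl, c_abs, c_scat, q_abs, q_scat, q_sc)


def scattering_efficiency(s: CrossSectionSpectrum, wavelength_nm: float
                          ) -> float:
    """Q_sc = C_scat / (C_scat + C_abs) at one grid wavelength."""
    row = s.at(wavelength_nm)
    denom = row["c_scat_nm2"] + row["c_abs_nm2"]
    if denom <= 0.0:
        raise ValueError(
            "scattering efficiency undefined: C_scat + C_abs = 0 at "
            f"{wavelength_nm} nm"
        )
    return row["c_scat_nm2"] / denom


def default_grid(start_nm: float = 300.0, stop_nm: float = 800.0,
                 step_nm: float = 1.0) -> np.ndarray:
    return np.arange(start_nm, stop_nm + 0.5 * step_nm, step_nm)


def find_lspr(p: ParticleSpec, wavelengths_nm=None) -> float:
    """Grid wavelength maximizing C_abs (ties broken toward shorter lambda).

    Raises if the maximum sits on the grid boundary, i.e. the resonance is
    not bracketed by the supplied grid.
    """
    wl = default_grid() if wavelengths_nm is None else np.atleast_1d(
        np.asarray(wavelengths_nm, dtype=float))
    spec = cross_sections(p, wl)
    i = int(np.argmax(spec.c_abs_nm2))  # argmax takes the first (shortest) tie
    if i == 0 or i == len(wl) - 1:
        raise ValueError(
            "resonance not bracketed: C_abs maximal at the grid boundary "
            f"({wl[i]:.1f} nm)"
        )
    return float(wl[i])
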