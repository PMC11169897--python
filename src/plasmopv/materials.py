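"""Optical-constant fixtures and device scenarios.

Every downstream stage obtains its permittivities from an
:class:`OpticalConstants` table, and its geometry/illumination from a
:class:`DeviceScenario`.  The packaged fixtures cover three materials:

``silver``
    Bulk silver n,k over 250-810 nm from a Drude-Lorentz parameterization,
    shipped as a static CSV and treated as a physical constant.
``active_blend``
    The PCPDTBT:PCBM bulk-heterojunction host.  Its real index is calibrated
    so the Froehlich condition Re(eps_m + 2 eps_s) = 0 against the silver
    fixture falls at 453 nm; its extinction index carries the calibrated
    absorption anchors (see :mod:`plasmopv.calibrate`).
``water``
    The tissue-facing medium, n = 1.33, k = 0 across the band.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

AVAILABLE_MATERIALS = ("silver", "active_blend", "water")

_WAVELENGTH_MIN_NM = 250.0
_WAVELENGTH_MAX_NM = 800.0


class MaterialError(ValueError):
    """Unknown material or wavelength outside the fixture table."""


@dataclass(frozen=True)
class OpticalConstants:
    """Wavelength-indexed refractive index (n) and extinction index (k).

    The relative permittivity is derived, never stored:
    ``eps = (n + i k)**2``.
    """

    material_name: str
    wavelengths_nm: np.ndarray
    n: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.n, dtype=float)
        k = np.asarray(self.k, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "k", k)
        if wl.ndim != 1 or len(wl) < 2:
            raise MaterialError("optical-constant table needs >= 2 wavelengths")
        if not (len(wl) == len(n) == len(k)):
            raise MaterialError("wavelength, n, k columns differ in length")
        if np.any(np.diff(wl) <= 0):
            raise MaterialError("wavelengths must be strictly increasing")
        if wl[0] > _WAVELENGTH_MIN_NM or wl[-1] < _WAVELENGTH_MAX_NM:
            raise MaterialError(
                f"table must cover {_WAVELENGTH_MIN_NM:.0f}-"
                f"{_WAVELENGTH_MAX_NM:.0f} nm, got {wl[0]:.1f}-{wl[-1]:.1f}"
            )
        if np.any(n <= 0):
            raise MaterialError("refractive index n must be > 0 everywhere")
        if np.any(k < 0):
            raise MaterialError("extinction index k must be >= 0 everywhere")

    # -- interpolation ----------------------------------------------------

    def _check_range(self, wavelength_nm: np.ndarray) -> None:
        wl = np.asarray(wavelength_nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if np.any(wl < lo) or np.any(wl > hi):
            raise MaterialError(
                f"wavelength outside {self.material_name} table range "
                f"[{lo:.1f}, {hi:.1f}] nm (no extrapolation)"
            )

    def nk_at(self, wavelength_nm):
        """Linearly interpolated (n, k) at the requested wavelength(s)."""
        self._check_range(wavelength_nm)
        wl = np.asarray(wavelength_nm, dtype=float)
        n = np.interp(wl, self.wavelengths_nm, self.n)
        k = np.interp(wl, self.wavelengths_nm, self.k)
        return n, k

    def permittivity(self, wavelength_nm):
        """Complex relative permittivity eps = (n + i k)^2.

        n and k are interpolated linearly (not eps itself); wavelengths
        outside the table raise :class:`MaterialError`.
        """
        n, k = self.nk_at(wavelength_nm)
        return (n + 1j * k) ** 2

    # -- tabular round trip ----------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        header = "wavelength_nm,n,k"
        data = np.column_stack([self.wavelengths_nm, self.n, self.k])
        np.savetxt(path, data, delimiter=",", header=header, comments="",
                   fmt="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, material_name: str | None = None
                 ) -> "OpticalConstants":
        raw = np.genfromtxt(path, delimiter=",", names=True)
        name = material_name or Path(path).stem
        return cls(
            material_name=name,
            wavelengths_nm=np.atleast_1d(raw["wavelength_nm"]),
            n=np.atleast_1d(raw["n"]),
            k=np.atleast_1d(raw["k"]),
        )


def _data_path(name: str):
    return resources.files("plasmopv.data").joinpath(name)


def load_optical_constants(material_name: str) -> OpticalConstants:
    """Load a packaged optical-constant fixture by material name."""
    if material_name not in AVAILABLE_MATERIALS:
        raise MaterialError(
            f"unknown material {material_name!r}; available: "
            + ", ".join(AVAILABLE_MATERIALS)
        )
    with resources.as_file(_data_path(f"{material_name}.csv")) as p:
        return OpticalConstants.from_csv(p, material_name)


def permittivity(oc: OpticalConstants, wavelength_nm):
    """Module-level convenience wrapper for ``oc.permittivity``."""
    return oc.permittivity(wavelength_nm)


def load_calibration() -> dict:
    """Frozen calibration constants (see calibration.json provenance block)."""
    with resources.as_file(_data_path("calibration.json")) as p:
        return json.loads(Path(p).read_text())


# ---------------------------------------------------------------------------
# Device scenarios
# ---------------------------------------------------------------------------

A_RADII_NM = (5.0, 7.5, 10.0)
FILL_FRACTIONS = (0.05, 0.075, 0.10)
K_GAPS_NM = (1.0, 1.5, 2.5, 5.0)
INTENSITIES_MW_MM2 = (0.26, 0.33)


@dataclass(frozen=True)
class DeviceScenario:
    """One full device configuration (geometry, illumination, dissociation).

    Defaults are the preferred configuration of the design study:
    r = 10 nm A-AgNPs at f_s = 10%, R = 25 nm / 1.5 nm-gap cathode array,
    453 nm light at 0.26 mW/mm^2.
    """

    a_radius_nm: float = 10.0
    fill_fraction: float = 0.10
    k_radius_nm: float = 25.0
    k_gap_nm: float = 1.5
    intensity_mW_mm2: float = 0.26
    wavelength_nm: float = 453.0
    layer_L_nm: float = 70.0
    donor_W_nm: float = 14.0
    acceptor_W_nm: float = 25.0
    cell_area_um2: float = 100.0 * 100.0
    p_bare: float = 0.7
    p_enhanced: float = 0.85
    include_k_term: bool = True
    include_a_term: bool = True

    def __post_init__(self) -> None:
        geometric = (
            "a_radius_nm", "k_radius_nm", "k_gap_nm", "layer_L_nm",
            "donor_W_nm", "acceptor_W_nm", "cell_area_um2",
        )
        for name in geometric:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.fill_fraction <= 0.10):
            raise ValueError(
                "fill_fraction must lie in [0, 0.10]; larger loadings damage "
                "the active layer and are outside the modelled regime"
            )
        if self.fill_fraction > 0 and not self.include_a_term:
            # allowed: A-term can be switched off for ablation runs
            pass
        for name in ("p_bare", "p_enhanced"):
            p = getattr(self, name)
            if not (0.0 < p <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.intensity_mW_mm2 < 0:
            raise ValueError("intensity_mW_mm2 must be >= 0")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength_nm must be positive")

    # -- configuration file I/O ------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeviceScenario":
        payload = yaml.safe_load(Path(path).read_text())
        if not isinstance(payload, dict):
            raise ValueError(f"scenario file {path} must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(
                f"unknown scenario keys: {sorted(unknown)}; known: {sorted(known)}"
            )
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    def replace(self, **kwargs) -> "DeviceScenario":
        payload = {f.name: getattr(self, f.name) for f in fields(self)}
        payload.update(kwargs)
        return DeviceScenario(**payload)


def bare_scenario(wavelength_nm: float = 453.0,
                  intensity_mW_mm2: float = 0.26) -> DeviceScenario:
    """The control device: no A-AgNPs, no cathode-array term."""
    return DeviceScenario(
        fill_fraction=0.0,
        include_k_term=False,
        include_a_term=False,
        wavelength_nm=wavelength_nm,
        intensity_mW_mm2=intensity_mW_mm2,
    )
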