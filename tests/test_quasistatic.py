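"""Quasi-static single-sphere optics: polarizability, cross-sections, LSPR."""

import numpy as np
import pytest

from plasmopv.materials import OpticalConstants, load_optical_constants
from plasmopv.quasistatic import (ParticleSpec, cross_sections, default_grid,
                                  find_lspr, polarizability,
                                  scattering_efficiency)

RADII = (5.0, 7.5, 10.0)


def _flat_table(name, n, k):
    wl = np.array([250.0, 810.0])
    return OpticalConstants(name, wl, np.full(2, n), np.full(2, k))


class TestPolarizability:
    def test_index_matched_vanishes(self):
        table = _flat_table("same", 1.5, 0.0)
        p = ParticleSpec(radius_nm=10.0)
        a = polarizability(p, 500.0, metal_table=table, medium_table=table)
        assert a == 0.0

    def test_volume_scaling(self):
        p1 = ParticleSpec(radius_nm=10.0)
        p2 = ParticleSpec(radius_nm=20.0)
        a1 = polarizability(p1, 500.0)
        a2 = polarizability(p2, 500.0)
        assert a2 == pytest.approx(8.0 * a1)

    def test_magnitude_maximal_at_resonance(self):
        p = ParticleSpec(radius_nm=10.0)
        wl = default_grid()
        a = polarizability(p, wl)
        # |alpha| peaks a few nm red of the C_abs peak (the 2*pi/lambda
        # weight and the declining host loss shift the two extrema apart)
        assert wl[int(np.argmax(np.abs(a)))] == pytest.approx(453.0, abs=10.0)

    def test_radius_above_dipole_limit_rejected(self):
        with pytest.raises(ValueError, match="quasi-static"):
            ParticleSpec(radius_nm=60.0)


class TestCrossSections:
    def test_brute_force_oracle(self, rng):
        """Direct composition of the polarizability and cross-section
        formulas from the fixture tables, independent of the module path."""
        silver = load_optical_constants("silver")
        blend = load_optical_constants("active_blend")
        for _ in range(20):
            r = rng.uniform(2.0, 50.0)
            wl = rng.uniform(260.0, 790.0)
            eps_m = silver.permittivity(wl)
            eps_s = blend.permittivity(wl)
            v = 4.0 / 3.0 * np.pi * r**3
            alpha = 3.0 * v * (eps_m - eps_s) / (eps_m + 2.0 * eps_s)
            c_abs = 2.0 * np.pi / wl * alpha.imag
            c_scat = (2.0 * np.pi / wl) ** 4 * abs(alpha) ** 2 / (6.0 * np.pi)
            spec = cross_sections(ParticleSpec(radius_nm=r), np.array([wl]))
            assert spec.c_abs_nm2[0] == pytest.approx(c_abs, rel=1e-12)
            assert spec.c_scat_nm2[0] == pytest.approx(c_scat, rel=1e-12)

    def test_lossless_offresonant_sphere_does_not_absorb(self):
        metal = _flat_table("lossless", 3.0, 0.0)
        medium = _flat_table("host", 1.5, 0.0)
        p = ParticleSpec(radius_nm=10.0)
        a = polarizability(p, 500.0, metal_table=metal, medium_table=medium)
        assert a.imag == 0.0

    def test_peak_efficiencies_increase_with_radius(self):
        peaks_abs, peaks_scat = [], []
        for r in RADII:
            spec = cross_sections(ParticleSpec(radius_nm=r), default_grid())
            peaks_abs.append(np.max(spec.q_abs))
            peaks_scat.append(np.max(spec.q_scat))
        assert np.all(np.diff(peaks_abs) > 0)
        assert np.all(np.diff(peaks_scat) > 0)

    def test_scat_to_abs_ratio_scales_with_volume(self):
        """Q_scat/Q_abs grows ~8x when the radius doubles (off resonance)."""
        wl = np.array([600.0])
        s1 = cross_sections(ParticleSpec(radius_nm=10.0), wl)
        s2 = cross_sections(ParticleSpec(radius_nm=20.0), wl)
        ratio1 = s1.q_scat[0] / s1.q_abs[0]
        ratio2 = s2.q_scat[0] / s2.q_abs[0]
        assert ratio2 / ratio1 == pytest.approx(8.0, rel=0.20)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cross_sections(ParticleSpec(radius_nm=10.0), np.array([]))

    def test_spectrum_invariants(self):
        spec = cross_sections(ParticleSpec(radius_nm=7.5), default_grid())
        assert np.all(spec.c_abs_nm2 >= 0)
        assert np.all(spec.c_scat_nm2 >= 0)
        assert np.all((spec.q_sc >= 0) & (spec.q_sc <= 1))
        total = spec.c_abs_nm2 + spec.c_scat_nm2
        expect = np.divide(spec.c_scat_nm2, total, where=total > 0,
                           out=np.zeros_like(total))
        assert np.allclose(spec.q_sc, expect)


class TestScatteringEfficiency:
    def test_zero_scattering_gives_zero(self):
        from plasmopv.quasistatic import CrossSectionSpectrum
        wl = np.array([453.0])
        spec = CrossSectionSpectrum(wl, np.array([100.0]), np.array([0.0]),
                                    np.array([1.0]), np.array([0.0]),
                                    np.array([0.0]))
        assert scattering_efficiency(spec, 453.0) == 0.0

    def test_printed_value_arithmetic(self):
        """Efficiency recomputed from the printed peak Q values."""
        assert 0.006 / (0.006 + 1.8) == pytest.approx(0.00332, abs=5e-6)

    def test_resonance_value_r75_one_sig_fig(self):
        p = ParticleSpec(radius_nm=7.5)
        spec = cross_sections(p, default_grid())
        q = scattering_efficiency(spec, find_lspr(p))
        assert float(f"{q:.1g}") == pytest.approx(0.003)

    def test_zero_denominator_rejected(self):
        metal = _flat_table("lossless", 3.0, 0.0)
        spec = cross_sections(ParticleSpec(radius_nm=10.0),
                              np.array([500.0]),
                              metal_table=metal,
                              medium_table=_flat_table("m", 3.0, 0.0))
        with pytest.raises(ValueError, match="undefined"):
            scattering_efficiency(spec, 500.0)


class TestLsprFinder:
    def test_silver_in_blend_resonates_at_design_wavelength(self):
        assert find_lspr(ParticleSpec(radius_nm=10.0)) == 453.0

    def test_water_host_shifts_resonance_blue(self):
        lspr_water = find_lspr(ParticleSpec(radius_nm=10.0, medium="water"))
        assert lspr_water < 453.0

    def test_unbracketed_resonance_rejected(self):
        grid = np.arange(500.0, 701.0, 1.0)  # excludes the 400-500 nm band
        with pytest.raises(ValueError, match="not bracketed"):
            find_lspr(ParticleSpec(radius_nm=10.0), grid)
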