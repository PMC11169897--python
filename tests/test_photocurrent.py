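"""Generation rate, bare J_sc and the three-term composite photocurrent."""

import numpy as np
import pytest

from plasmopv import units
from plasmopv.materials import DeviceScenario, bare_scenario, load_calibration
from plasmopv.photocurrent import (generation_rate, jsc_bare, jsc_composite,
                                   volume_ratio_v1, volume_ratio_v2)

GRID_026_WITH_K = {  # printed peak J_sc at 0.26 mW/mm^2, with cathode term
    (5.0, 0.05): 15, (5.0, 0.075): 17, (5.0, 0.10): 20,
    (7.5, 0.05): 20, (7.5, 0.075): 24, (7.5, 0.10): 29,
    (10.0, 0.05): 25, (10.0, 0.075): 32, (10.0, 0.10): 39,
}
GRID_033_WITHOUT_K = {(7.5, 0.05): 22, (7.5, 0.075): 27, (7.5, 0.10): 33}
GRID_033_WITH_K = {(7.5, 0.05): 25, (7.5, 0.075): 30, (7.5, 0.10): 36}


class TestGenerationRate:
    def test_dark_means_no_generation(self):
        assert generation_rate(1e6, 453.0, 0.0, 0.7) == 0.0

    def test_linear_in_intensity(self):
        g1 = generation_rate(1e6, 453.0, 260.0, 0.7)
        g2 = generation_rate(1e6, 453.0, 520.0, 0.7)
        assert g2 == pytest.approx(2.0 * g1, rel=1e-12)

    def test_dimensional_anchor(self):
        """alpha ~ 1.7e6 1/m at 453 nm / 260 W/m^2 / P=0.7 gives G q L of
        a few A/m^2 (the bare-device scale)."""
        g = generation_rate(1.7e6, 453.0, 260.0, 0.7)
        jsc = g * units.ELEMENTARY_CHARGE_C * 70e-9
        assert 5.0 < jsc < 10.0

    def test_invalid_dissociation_probability(self):
        with pytest.raises(ValueError):
            generation_rate(1e6, 453.0, 260.0, 0.0)


class TestBareJsc:
    def test_printed_values_both_wavelengths(self):
        assert jsc_bare(bare_scenario()) == pytest.approx(7.5, abs=0.01)
        assert jsc_bare(bare_scenario(250.0)) == pytest.approx(19.0, abs=0.05)
        assert jsc_bare(bare_scenario(453.0, 0.33)) == pytest.approx(9.5,
                                                                     abs=0.05)

    def test_dark_device(self):
        assert jsc_bare(bare_scenario(453.0, 0.0)) == 0.0


class TestVolumeRatios:
    def test_v1_unit_absorption_disc(self):
        assert volume_ratio_v1(1.0) == 1.0

    def test_v1_hand_arithmetic(self):
        assert volume_ratio_v1(2.4) == pytest.approx(2.4**1.5, rel=1e-12)
        assert volume_ratio_v1(2.4) == pytest.approx(3.72, abs=0.01)

    def test_v1_radius_scaling_matches_printed_slopes(self):
        """v1 ratios across r = 5/7.5/10 reproduce the 1 : 1.8 : 2.8 slope
        ratios of the printed J_sc-vs-f_s grids."""
        v = np.array([volume_ratio_v1(q) for q in (1.2, 1.8, 2.4)])
        ratios = v / v[0]
        slopes = []
        for r in (5.0, 7.5, 10.0):
            j = [GRID_026_WITH_K[(r, f)] for f in (0.05, 0.075, 0.10)]
            slopes.append(np.polyfit([0.05, 0.075, 0.10], j, 1)[0])
        printed = np.array(slopes) / slopes[0]
        assert ratios == pytest.approx(printed, rel=0.05)

    def test_v2_trivials(self, preferred_scenario):
        assert volume_ratio_v2(0.0, preferred_scenario) == 0.0
        full = volume_ratio_v2(1500.0, preferred_scenario)
        assert volume_ratio_v2(750.0, preferred_scenario) == (
            pytest.approx(full / 2, rel=1e-12))

    def test_v2_against_brute_force_site_count(self, preferred_scenario):
        """Count staggered-lattice sites in the 100x100 um^2 cell directly."""
        pitch = 51.5
        nx = int(100e3 / pitch) + 2
        ny = int(100e3 / (pitch * np.sqrt(3) / 2)) + 2
        count = 0
        for j in range(ny):
            y = j * pitch * np.sqrt(3) / 2
            if y >= 100e3:
                continue
            x0 = (pitch / 2) if (j % 2) else 0.0
            count += len(np.arange(x0, 100e3, pitch))
        v2_brute = count * 1500.0 * 25.0 / (100e3 * 100e3 * 70.0)
        v2 = volume_ratio_v2(1500.0, preferred_scenario)
        assert v2 == pytest.approx(v2_brute, rel=0.01)


class TestComposite:
    def test_degenerates_to_bare(self, bare_453):
        b = jsc_composite(bare_453)
        assert b.jsc_total == pytest.approx(jsc_bare(bare_453), rel=1e-12)
        assert b.term_a_np == 0.0 and b.term_k_np == 0.0

    def test_terms_sum_and_signs(self, preferred_scenario):
        b = jsc_composite(preferred_scenario)
        assert b.jsc_total == pytest.approx(
            b.term_bare + b.term_a_np + b.term_k_np, rel=1e-12)
        assert min(b.term_bare, b.term_a_np, b.term_k_np) >= 0
        assert 0.0 <= b.k_coeff <= 1.0

    def test_linear_in_intensity(self, preferred_scenario):
        j1 = jsc_composite(preferred_scenario).jsc_total
        j2 = jsc_composite(
            preferred_scenario.replace(intensity_mW_mm2=0.52)).jsc_total
        assert j2 == pytest.approx(2.0 * j1, rel=1e-9)

    def test_monotone_in_radius_and_fill_fraction(self):
        grid = {}
        for r in (5.0, 7.5, 10.0):
            for f in (0.05, 0.075, 0.10):
                grid[(r, f)] = jsc_composite(
                    DeviceScenario(a_radius_nm=r, fill_fraction=f)).jsc_total
        for f in (0.05, 0.075, 0.10):
            assert grid[(5.0, f)] < grid[(7.5, f)] < grid[(10.0, f)]
        for r in (5.0, 7.5, 10.0):
            assert grid[(r, 0.05)] < grid[(r, 0.075)] < grid[(r, 0.10)]

    def test_k_term_contribution_nearly_constant_in_fill_fraction(self):
        """(with-K minus without-K) J_sc varies < 15% across f_s."""
        deltas = []
        for f in (0.05, 0.075, 0.10):
            scn = DeviceScenario(a_radius_nm=10.0, fill_fraction=f)
            with_k = jsc_composite(scn).jsc_total
            without = jsc_composite(scn.replace(include_k_term=False)).jsc_total
            deltas.append(with_k - without)
        assert (max(deltas) - min(deltas)) / np.mean(deltas) < 0.15

    def test_calibrate_then_predict_printed_grids(self):
        """kappa_A is fitted only at (r=5, f_s=5%) and kappa_K only at one
        with/without pair; the other printed values must follow within
        +-2 A/m^2."""
        for (r, f), ref in GRID_026_WITH_K.items():
            j = jsc_composite(
                DeviceScenario(a_radius_nm=r, fill_fraction=f)).jsc_total
            assert j == pytest.approx(ref, abs=2.0), (r, f)
        for grid, with_k in ((GRID_033_WITHOUT_K, False),
                             (GRID_033_WITH_K, True)):
            for (r, f), ref in grid.items():
                scn = DeviceScenario(a_radius_nm=r, fill_fraction=f,
                                     intensity_mW_mm2=0.33,
                                     include_k_term=with_k)
                assert jsc_composite(scn).jsc_total == pytest.approx(
                    ref, abs=2.0), (r, f, with_k)

    def test_frozen_calibration_reproduces_anchors(self):
        calib = load_calibration()
        anchor1 = jsc_composite(
            DeviceScenario(a_radius_nm=5.0, fill_fraction=0.05), calib)
        assert anchor1.jsc_total == pytest.approx(15.0, abs=1e-6)
        pair = DeviceScenario(a_radius_nm=7.5, fill_fraction=0.05,
                              intensity_mW_mm2=0.33)
        delta = (jsc_composite(pair, calib).jsc_total
                 - jsc_composite(pair.replace(include_k_term=False),
                                 calib).jsc_total)
        assert delta == pytest.approx(3.0, abs=1e-6)
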