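"""Contraction strains, springs-in-series stiffness, rest length."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from envmorph import (PlasmolysisTriplet, StrainPreset,
                      gen_plasmolysis_triplets, om_rest_length,
                      om_surface_area, percent_stiffness_reduction,
                      plasmolyzed_ratio, stiffness_ratio, strains)
from envmorph.mechanics import StiffnessEstimate

pos = st.floats(0.1, 10.0, allow_nan=False)


class TestStrains:
    def test_parent_like_triplet(self):
        s = strains(PlasmolysisTriplet(1.2432, 1.11, 1.0))
        assert s.eps12 == pytest.approx(0.12)
        assert s.eps23 == pytest.approx(0.11)
        assert s.eps13 == pytest.approx(0.2432)

    def test_equal_lengths_zero_strain(self):
        s = strains(PlasmolysisTriplet(2.0, 2.0, 2.0))
        assert (s.eps12, s.eps23, s.eps13) == (0.0, 0.0, 0.0)

    def test_composition_identity_example(self):
        s = strains(PlasmolysisTriplet(1.3, 1.0, 0.975))
        assert s.eps12 == pytest.approx(0.3)
        assert s.eps23 == pytest.approx(0.025641, abs=1e-6)
        assert s.eps13 == pytest.approx(1.3 / 0.975 - 1)
        assert (1 + s.eps12) * (1 + s.eps23) == pytest.approx(1 + s.eps13)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(l1=pos, l2=pos, l3=pos)
    def test_composition_identity_property(self, l1, l2, l3):
        s = strains(PlasmolysisTriplet(l1, l2, l3))
        assert (1 + s.eps13) == pytest.approx((1 + s.eps12) * (1 + s.eps23),
                                              rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(l1=pos, l2=pos, l3=pos, c=st.floats(0.01, 100.0))
    def test_scale_invariance(self, l1, l2, l3, c):
        s1 = strains(PlasmolysisTriplet(l1, l2, l3))
        s2 = strains(PlasmolysisTriplet(c * l1, c * l2, c * l3))
        assert s2.eps12 == pytest.approx(s1.eps12, rel=1e-9, abs=1e-12)
        assert s2.eps23 == pytest.approx(s1.eps23, rel=1e-9, abs=1e-12)

    def test_elongating_cell_flagged_not_dropped(self):
        s = strains(PlasmolysisTriplet(1.0, 1.1, 1.0))
        assert s.flagged
        assert s.eps12 < 0

    def test_missing_lysed_length(self):
        s = strains(PlasmolysisTriplet(1.2, 1.0))
        assert s.eps12 == pytest.approx(0.2)
        assert s.eps23 is None and s.eps13 is None

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            strains(PlasmolysisTriplet(1.0, -1.0, 1.0))


class TestStiffnessRatio:
    def test_hand_arithmetic(self):
        # k = <e23> / (<e12> (1 + <e23>)) = 0.11 / (0.12 * 1.11)
        est = stiffness_ratio([PlasmolysisTriplet(1.2432, 1.11, 1.0)])
        assert est.k_ratio == pytest.approx(0.11 / (0.12 * 1.11), abs=1e-9)
        assert est.k_ratio == pytest.approx(0.8258, abs=1e-4)

    def test_zero_lysis_contraction_zero_stiffness(self):
        est = stiffness_ratio([PlasmolysisTriplet(1.2, 1.0, 1.0)])
        assert est.k_ratio == 0.0

    def test_equal_strains_limit(self):
        for x in (0.3, 0.1, 0.01, 1e-4):
            l2 = 1 + x
            l1 = l2 * (1 + x)
            est = stiffness_ratio([PlasmolysisTriplet(l1, l2, 1.0)])
            assert est.k_ratio == pytest.approx(1 / (1 + x), rel=1e-9)

    def test_monotone_in_both_mean_strains(self):
        # increasing in <e23>, decreasing in <e12>, on a 20x20 grid
        e12s = np.linspace(0.05, 0.5, 20)
        e23s = np.linspace(0.01, 0.4, 20)
        k = np.empty((20, 20))
        for i, e12 in enumerate(e12s):
            for j, e23 in enumerate(e23s):
                l3, l2 = 1.0, 1.0 + e23
                l1 = l2 * (1 + e12)
                k[i, j] = stiffness_ratio([PlasmolysisTriplet(l1, l2, l3)]).k_ratio
        assert np.all(np.diff(k, axis=1) > 0)   # in e23
        assert np.all(np.diff(k, axis=0) < 0)   # in e12

    def test_partial_triplets_count_toward_eps12_only(self):
        trips = [PlasmolysisTriplet(1.2432, 1.11, 1.0),
                 PlasmolysisTriplet(1.3, 1.0)]  # no lysed length
        est = stiffness_ratio(trips)
        assert est.n_full == 1 and est.n_eps12_only == 1
        assert est.mean_eps12 == pytest.approx((0.12 + 0.3) / 2)
        assert est.mean_eps23 == pytest.approx(0.11)

    def test_parameter_recovery_noisy_preset(self):
        preset = StrainPreset("p", 0.12, 0.11, noise_cv=0.02, n_cells=24)
        trips = gen_plasmolysis_triplets(preset, seed=3)
        est = stiffness_ratio(trips)
        # 2 SE of the mean strain: noise on a ratio of two lognormals
        se = 0.02 * np.sqrt(2) / np.sqrt(24)
        assert abs(est.mean_eps12 - 0.12) < 2 * se * (1 + 0.12)
        assert abs(est.mean_eps23 - 0.11) < 2 * se * (1 + 0.11)

    def test_percent_reduction(self):
        parent = StiffnessEstimate(0.8, 0.12, 0.11, 17, 0)
        mutant = StiffnessEstimate(0.08, 0.30, 0.02, 24, 6)
        assert percent_stiffness_reduction(mutant, parent) == pytest.approx(90.0)


class TestRestLength:
    def test_unit_circle_pancake(self):
        # a = pi, s = 2 pi, w = 1 -> A_OM = 2 pi + 2 pi = 4 pi
        assert om_surface_area((np.pi, 2 * np.pi, 1.0)) == pytest.approx(4 * np.pi)

    def test_zero_height_limit(self):
        assert om_surface_area((3.0, 10.0, 0.0)) == pytest.approx(6.0)

    def test_matched_areas_identity(self):
        res = om_rest_length(A_OM=12.0, A_turgid=12.0, l_turgid=4.0, w=1.0)
        assert res.l_OM == pytest.approx(4.0)
        assert res.ratio_rest_to_turgid == pytest.approx(1.0)

    def test_spherocylinder_surplus_algebra(self):
        # A_turgid = pi w l, A_OM = pi w (l + delta)  =>  l_OM = l + delta
        w, l, delta = 0.9, 5.0, 1.7
        res = om_rest_length(A_OM=np.pi * w * (l + delta),
                             A_turgid=np.pi * w * l, l_turgid=l, w=w)
        assert res.l_OM == pytest.approx(l + delta, rel=1e-12)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            om_rest_length(12.0, 12.0, 4.0, 0.0)


class TestPlasmolyzedRatio:
    @pytest.mark.parametrize("eps12, expected", [
        (0.30, 1 / 1.30),   # ~77 %, the "~75 % of turgid length" regime
        (0.0, 1.0),
        (0.12, 1 / 1.12),
    ])
    def test_values(self, eps12, expected):
        assert plasmolyzed_ratio(eps12) == pytest.approx(expected)

    def test_domain_edge_rejected(self):
        with pytest.raises(ValueError):
            plasmolyzed_ratio(-1.0)
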