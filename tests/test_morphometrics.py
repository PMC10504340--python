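"""Growth rates, width CV, shape groups, rupture calls, viability."""

import numpy as np
import pytest
from scipy import stats

from envmorph import (CellTrack, FluorTrace, GrowthTrackSpec, RodSpec,
                      RuptureCall, TraceSpec, call_rupture, gen_fluor_trace,
                      gen_growth_track, gen_rod_contour, group_by_shape,
                      instantaneous_growth_rate, mesh_contour,
                      viability_fraction, width_cv)
from envmorph.contours import CenterlineMesh
from envmorph.morphometrics import WidthStats


def _mesh_from_widths(widths):
    """Minimal mesh carrying a given non-pole width profile."""
    w = np.asarray(widths, float)
    n = len(w) + 2
    s = np.linspace(0, 10, n)
    widths_full = np.concatenate([[0.2], w, [0.2]])
    is_pole = np.zeros(n, bool)
    is_pole[0] = is_pole[-1] = True
    pts = np.column_stack([s, np.zeros(n)])
    return CenterlineMesh(points=pts, widths=widths_full, arclength=s,
                          is_pole=is_pole, cell_length=10.0,
                          mean_width=float(w.mean()))


class TestGrowthRate:
    def test_exact_exponential_recovered_everywhere(self):
        tr = gen_growth_track(GrowthTrackSpec(area0=2, rate_true=0.02,
                                              n_frames=101))
        out = instantaneous_growth_rate(tr, window=5)
        np.testing.assert_allclose(out[:, 1], 0.02, atol=1e-10)

    def test_constant_area_zero_rate(self):
        tr = CellTrack("c", np.arange(20.0), np.full(20, 3.0))
        out = instantaneous_growth_rate(tr)
        np.testing.assert_allclose(out[:, 1], 0.0, atol=1e-12)

    def test_doubling_time_30min(self):
        t = np.arange(0, 61.0)
        tr = CellTrack("c", t, 2 ** (t / 30.0))
        out = instantaneous_growth_rate(tr, window=5)
        np.testing.assert_allclose(out[:, 1], np.log(2) / 30, atol=1e-6)

    def test_area_rescaling_invariance(self):
        tr = gen_growth_track(GrowthTrackSpec(area0=2, rate_true=0.015,
                                              noise_cv=0.03, seed=9, n_frames=50))
        r1 = instantaneous_growth_rate(tr)[:, 1]
        tr2 = CellTrack(tr.cell_id, tr.times, tr.areas * 7.3)
        r2 = instantaneous_growth_rate(tr2)[:, 1]
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_nonpositive_area_rejected(self):
        tr = CellTrack("c", np.arange(5.0), np.array([1, 1, 0, 1, 1.0]))
        with pytest.raises(ValueError):
            instantaneous_growth_rate(tr)


class TestWidthCV:
    def test_uniform_widths_zero_cv(self):
        ws = width_cv(_mesh_from_widths(np.ones(20)))
        assert ws.width_cv == 0.0

    def test_three_level_profile(self):
        # sample SD of {0.9, 1.0, 1.1} is 0.1, mean 1.0 -> CV 0.1
        ws = width_cv(_mesh_from_widths([0.9, 1.0, 1.1] * 5))
        sd = np.std([0.9, 1.0, 1.1] * 5, ddof=1)
        assert ws.width_cv == pytest.approx(sd / 1.0)

    def test_noiseless_spherocylinder_pipeline_cv_small(self, mesh_4x1):
        assert width_cv(mesh_4x1).width_cv < 0.01

    def test_scale_invariance_through_pipeline(self, rod_4x1, mesh_4x1):
        big = rod_4x1.transformed(scale=3.0, rotation=0.5)
        cv_big = width_cv(mesh_contour(big)).width_cv
        assert cv_big == pytest.approx(width_cv(mesh_4x1).width_cv, abs=1e-3)

    def test_too_few_stations_rejected(self):
        with pytest.raises(ValueError, match="non-pole"):
            width_cv(_mesh_from_widths([1.0, 1.0, 1.0]))


class TestGroupByShape:
    @staticmethod
    def _cells(cvs, rates):
        return [(WidthStats(1.0, cv, 30), r) for cv, r in zip(cvs, rates)]

    def test_identical_groups_ks_p_one(self):
        rates = np.linspace(0.01, 0.02, 20)
        cells = self._cells(np.r_[np.full(20, 0.02), np.full(20, 0.10)],
                            np.r_[rates, rates])
        out = group_by_shape(cells, bin_edges=[0.05])
        (_, stat, p), = out.ks_adjacent
        assert stat == 0.0
        assert p == 1.0

    def test_location_shift_detected_vs_permutation_oracle(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0.020, 0.002, 50)
        b = a - 0.010  # large shift: slow-growing misshapen group
        cells = self._cells(np.r_[np.full(50, 0.02), np.full(50, 0.12)],
                            np.r_[a, b])
        out = group_by_shape(cells, bin_edges=[0.06])
        (_, stat, p), = out.ks_adjacent
        assert p < 1e-3
        # independent permutation oracle on the KS statistic
        pooled = np.r_[a, b]
        n_extreme = 0
        n_perm = 2000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            d = stats.ks_2samp(pooled[:50], pooled[50:]).statistic
            n_extreme += d >= stat
        assert (n_extreme + 1) / (n_perm + 1) < 1e-3

    def test_group_sizes_reported(self):
        cells = self._cells([0.02] * 7 + [0.10] * 13,
                            list(np.linspace(0.01, 0.02, 7)) +
                            list(np.linspace(0.005, 0.015, 13)))
        out = group_by_shape(cells, bin_edges=[0.05])
        assert [g.n for g in out.groups] == [7, 13]

    def test_empty_group_dropped_with_warning(self):
        cells = self._cells([0.02] * 10 + [0.10] * 10, np.linspace(0, 1, 20))
        with pytest.warns(UserWarning, match="empty"):
            out = group_by_shape(cells, bin_edges=[0.05, 0.5])
        assert len(out.groups) == 2


class TestCallRupture:
    def test_om_first_with_15min_gap(self):
        # OM ruptures first: cytoplasmic marker outlives the periplasmic one
        tr = gen_fluor_trace(TraceSpec(t_loss_periplasm=10, t_loss_cytoplasm=25,
                                       n_frames=50))
        call = call_rupture(tr)
        assert call.order == "OM_first"
        assert call.t_loss_cytoplasm - call.t_loss_periplasm == pytest.approx(
            15.0, abs=1.5)

    def test_no_loss_is_none(self):
        call = call_rupture(gen_fluor_trace(TraceSpec(n_frames=20)))
        assert call.order == "none"
        assert call.t_loss_periplasm is None

    def test_simultaneous_losses_coincident(self):
        tr = gen_fluor_trace(TraceSpec(t_loss_periplasm=15, t_loss_cytoplasm=15,
                                       n_frames=40))
        assert call_rupture(tr).order == "coincident"

    def test_loss_times_recovered_within_one_frame_under_noise(self):
        for seed in range(10):
            tr = gen_fluor_trace(TraceSpec(t_loss_periplasm=12,
                                           t_loss_cytoplasm=30,
                                           noise_sd=0.05,
                                           n_frames=60, seed=seed))
            call = call_rupture(tr)
            assert call.order == "OM_first"
            assert call.t_loss_periplasm == pytest.approx(12, abs=1.0)
            assert call.t_loss_cytoplasm == pytest.approx(30, abs=1.0)

    def test_transient_dip_is_not_a_loss(self):
        t = np.arange(20.0)
        peri = np.ones(20)
        peri[8] = 0.1  # one-frame dip, recovers
        tr = FluorTrace("c", t, peri, np.ones(20))
        assert call_rupture(tr).order == "none"

    def test_short_trace_rejected(self):
        tr = FluorTrace("c", np.arange(2.0), np.ones(2), np.ones(2))
        with pytest.raises(ValueError):
            call_rupture(tr)


class TestViability:
    def test_all_intact_fraction_one(self):
        calls = [RuptureCall(None, None, "none")] * 5
        assert viability_fraction(calls) == (1.0, 5)

    def test_lysis_flags(self):
        # 3 of 4 lysed -> 0.25 viable
        assert viability_fraction([True, True, True, False]) == (0.25, 4)

    def test_im_first_fraction_zero_for_om_first_population(self):
        calls = []
        for seed in range(30):
            tr = gen_fluor_trace(TraceSpec(t_loss_periplasm=10 + seed % 5,
                                           t_loss_cytoplasm=20 + seed % 7,
                                           noise_sd=0.05, n_frames=60,
                                           seed=seed))
            calls.append(call_rupture(tr))
        assert sum(c.order == "IM_first" for c in calls) == 0
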