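"""Regional metrics, time-point selection, windowing, Reynolds numbers."""

import numpy as np
import pytest

from flowtke.geometry import SegmentationSet, VolumeCurve
from flowtke.hemodynamics import (
    PhysicalConstants,
    detect_timepoints,
    frame_metrics,
    median_filter_3,
    reynolds,
    subject_summary,
    window_average,
)


def _seg_one_region(mask4, region="LV", voxel_size=2.8):
    return SegmentationSet(masks={region: mask4}, voxel_size=voxel_size)


class TestFrameMetrics:
    def test_uniform_tke_integration(self):
        shape = (12, 12, 12, 1)
        mask = np.zeros(shape, bool)
        mask.reshape(-1)[:1000] = True
        tke = np.full(shape, 100.0)
        speed = np.zeros(shape)
        fm = frame_metrics(tke, speed, _seg_one_region(mask), "LV")
        assert np.isclose(fm.tke_tot[0], 100 * 1000 * (2.8e-3) ** 3 * 1e3)  # 2.195 mJ
        assert np.isclose(fm.tke_max[0], 100.0)  # median filter is identity on constants

    def test_single_voxel_spike_suppressed(self):
        shape = (9, 9, 9, 1)
        mask = np.ones(shape, bool)
        tke = np.zeros(shape)
        tke[4, 4, 4, 0] = 1000.0
        speed = np.zeros(shape)
        fm = frame_metrics(tke, speed, _seg_one_region(mask), "LV")
        assert fm.tke_max[0] == 0.0
        # brute-force 27-neighborhood median at the spike
        nb = tke[3:6, 3:6, 3:6, 0].ravel()
        assert np.median(nb) == 0.0

    def test_velocity_stats(self):
        shape = (6, 6, 6, 2)
        mask = np.ones(shape, bool)
        rng = np.random.default_rng(0)
        speed = rng.uniform(0, 2, shape)
        fm = frame_metrics(np.zeros(shape), speed, _seg_one_region(mask), "LV")
        for t in range(2):
            assert np.isclose(fm.vel_avg[t], speed[..., t].mean())
            assert np.isclose(fm.vel_max[t], speed[..., t].max())
            assert fm.vel_avg[t] <= fm.vel_max[t]

    def test_tke_tot_additive_over_partitions(self):
        shape = (8, 8, 8, 1)
        rng = np.random.default_rng(1)
        tke = rng.uniform(0, 300, shape)
        speed = np.zeros(shape)
        whole = np.ones(shape, bool)
        left, right = whole.copy(), whole.copy()
        left[4:] = False
        right[:4] = False
        tot = lambda m: frame_metrics(tke, speed, _seg_one_region(m), "LV").tke_tot[0]
        assert np.isclose(tot(left) + tot(right), tot(whole))

    def test_grid_mismatch_rejected(self):
        mask = np.ones((6, 6, 6, 2), bool)
        with pytest.raises(ValueError):
            frame_metrics(np.zeros((6, 6, 6, 3)), np.zeros((6, 6, 6, 2)),
                          _seg_one_region(mask), "LV")


class TestMedianFilter:
    def test_constant_unchanged(self):
        f = np.full((7, 7, 7), 3.3)
        assert np.array_equal(median_filter_3(f), f)

    def test_isolated_spike_removed_matches_brute_force(self):
        rng = np.random.default_rng(2)
        f = rng.uniform(0, 1, (7, 7, 7))
        f[3, 3, 3] = 50.0
        out = median_filter_3(f)
        assert out[3, 3, 3] == np.median(f[2:5, 2:5, 2:5])
        assert out[3, 3, 3] < 2.0

    def test_monotone_ramp_interior_unchanged(self):
        z = np.arange(9, dtype=float)
        f = np.broadcast_to(z, (9, 9, 9)).copy()
        out = median_filter_3(f)
        assert np.allclose(out[1:-1, 1:-1, 1:-1], f[1:-1, 1:-1, 1:-1])


class TestTimepoints:
    def test_sinusoid_matches_brute_force(self):
        n = 40
        t = np.arange(n)
        v = 100 - 30 * np.sin(2 * np.pi * t / n)
        vc = VolumeCurve(region="LV", volumes=v)
        sys_f, early_f = detect_timepoints(vc)
        dv = (np.roll(v, -1) - np.roll(v, 1)) / 2
        assert sys_f == int(np.argmin(dv))
        t_min = int(np.argmin(v))
        t_max = int(np.argmax(v))
        dist = (t_max - t_min) % n
        window = [(t_min + k) % n for k in range(1, max(1, dist // 2) + 1)]
        assert early_f == window[int(np.argmax(dv[window]))]

    def test_e_wave_preferred_over_a_wave(self):
        # biphasic filling: E-wave slope 3x the A-wave slope
        v = np.array([100, 80, 60, 50, 50, 65, 80, 80, 85, 90, 95, 100.0])
        vc = VolumeCurve(region="LV", volumes=v)
        _, early_f = detect_timepoints(vc)
        assert early_f in (4, 5)  # on the E-wave upstroke, not the late A ramp

    def test_constant_curve_rejected(self):
        with pytest.raises(ValueError, match="constant|degenerate"):
            detect_timepoints(VolumeCurve(region="LV", volumes=np.full(12, 80.0)))

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            detect_timepoints(VolumeCurve(region="LV", volumes=np.arange(5.0) + 1))


class TestWindowAverage:
    def test_constant_series(self):
        assert window_average(np.full(10, 4.2), 5) == 4.2

    def test_arithmetic_mean(self):
        assert window_average(np.array([0.0, 3.0, 6.0]), 1) == 3.0

    def test_cyclic_edge(self):
        s = np.zeros(40)
        s[39], s[0], s[1] = 3.0, 6.0, 9.0
        assert window_average(s, 0) == 6.0

    def test_width_scales_with_frame_count(self):
        # 2.5% of 80 frames = 2 frames per side
        s = np.zeros(80)
        s[8:13] = 1.0
        assert window_average(s, 10) == 1.0
        assert window_average(np.roll(s, 1), 10) == 0.8

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            window_average(np.array([1.0, 2.0]), 0)


class TestReynolds:
    def test_closed_form(self):
        assert np.isclose(reynolds(1.5, 0.03), 11925.0)

    def test_zero_and_linearity(self):
        assert reynolds(0.0, 0.05) == 0.0
        assert np.isclose(reynolds(2.0, 0.03), 2 * reynolds(1.0, 0.03))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            reynolds(-0.1, 0.03)

    def test_constants_bounds(self):
        with pytest.raises(ValueError):
            PhysicalConstants(rho=500.0)
        with pytest.raises(ValueError):
            PhysicalConstants(mu=0.1)


class TestSubjectSummary:
    def test_matches_ground_truth_oracle(self, small_phantom):
        import flowtke as ft

        acq, seg, truth = small_phantom
        summary, _ = ft.quantify(acq, seg, static_mask=truth.static_mask,
                                 body_mask=truth.body_mask)
        oracle = subject_summary(truth.true_region_metrics, seg,
                                 summary.systole_frame, summary.early_diastole_frame)
        for region, rs in summary.regions.items():
            os_ = oracle.regions[region]
            for f in ("tke_tot", "tke_max", "vel_avg", "vel_max",
                      "mean_diam", "max_diam", "re_avg", "re_max"):
                a, b = getattr(rs, f), getattr(os_, f)
                assert abs(a - b) <= 1e-9 * max(abs(b), 1e-12), (region, f)

    def test_hot_frame_uses_window_not_raw_peak(self):
        # single hot frame: summary must reflect the +/-1-frame average
        n = 5
        mask = np.ones((8, 8, 8, n), bool)
        mask[..., :] = True
        tke = np.zeros((8, 8, 8, n))
        tke[..., 2] = 90.0
        speed = np.zeros((8, 8, 8, n))
        speed[..., 2] = 0.9
        seg = SegmentationSet(masks={"LV": mask}, voxel_size=2.8)
        fm = frame_metrics(tke, speed, seg, "LV")
        sm = subject_summary({"LV": fm}, seg, systole_frame=2, early_diastole_frame=2)
        assert np.isclose(sm.regions["LV"].vel_max, 0.3)  # (0 + 0.9 + 0)/3
        assert sm.regions["LV"].vel_max < fm.vel_max.max()

    def test_all_zero_fields_give_zero_metrics(self):
        n = 6
        mask = np.ones((8, 8, 8, n), bool)
        seg = SegmentationSet(masks={"LV": mask, "LA": mask.copy()}, voxel_size=2.8)
        fm = {r: frame_metrics(np.zeros((8, 8, 8, n)), np.zeros((8, 8, 8, n)), seg, r)
              for r in ("LV", "LA")}
        sm = subject_summary(fm, seg, systole_frame=1, early_diastole_frame=3)
        for r in ("LV", "LA"):
            assert sm.regions[r].tke_tot == 0.0
            assert sm.regions[r].re_avg == 0.0

    def test_missing_region_flagged_absent(self):
        n = 6
        mask = np.ones((8, 8, 8, n), bool)
        seg = SegmentationSet(masks={"LV": mask}, voxel_size=2.8)
        fm = {"LV": frame_metrics(np.zeros((8, 8, 8, n)), np.zeros((8, 8, 8, n)), seg, "LV")}
        sm = subject_summary(fm, seg, 1, 3)
        assert "RA" in sm.absent and "LV" in sm.regions
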