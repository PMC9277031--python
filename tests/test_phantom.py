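"""Synthetic-data generator: schedules, geometry fidelity, determinism, I/O."""

import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.signal import find_peaks

from seedoct.phantom import (TABLE_MEAN_UM, TABLE_TIMES_H, EventTimes,
                             PhantomConfig, WeightSeries, render_bscan,
                             render_camera_image, simulate_cohort,
                             simulate_timecourse, simulate_weight,
                             weight_schedule)
from seedoct.stats import align_series, pearson_r


def noise_free(config: PhantomConfig, **overrides) -> PhantomConfig:
    """Speckle off, flat roughness; optionally flat surface."""
    return replace(config, speckle_contrast=0.0,
                   roughness_values_um=tuple(0.0 for _ in config.roughness_values_um),
                   **overrides)


class TestSchedules:
    def test_default_schedule_has_240_time_points(self, config):
        assert len(simulate_timecourse(config, n_weight_seeds=1)) == 240

    def test_zero_duration_gives_empty_series(self, config):
        tc = simulate_timecourse(replace(config, duration_h=0.0), n_weight_seeds=1)
        assert len(tc) == 0
        assert all(v is None for v in tc.truth.event_times.values())

    def test_one_hour_at_ten_minutes_gives_six_points(self, config):
        tc = simulate_timecourse(replace(config, duration_h=1.0), n_weight_seeds=1)
        assert len(tc) == 6

    def test_weight_schedule_matches_protocol(self):
        t = weight_schedule(40.0)
        assert t[0] == 0.0 and t[-1] == 40.0
        dense = t[t <= 10.0]
        np.testing.assert_allclose(np.diff(dense), 0.5)
        sparse = t[t > 10.0]
        np.testing.assert_allclose(np.diff(sparse), 5.0)

    def test_non_monotone_thickness_rejected_with_time(self):
        with pytest.raises(ValueError, match="12"):
            PhantomConfig(thickness_times_h=(0.0, 6.0, 12.0),
                          thickness_values_um=(100.0, 150.0, 140.0))

    def test_crack_before_radicle_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(events=EventTimes(radicle_h=20.0, crack_h=10.0))


class TestDefaultThicknessCurve:
    def test_passes_through_every_table_pair(self, config):
        curve = config.thickness_curve()
        np.testing.assert_allclose(curve(TABLE_TIMES_H), TABLE_MEAN_UM, atol=1.0)

    def test_curve_nondecreasing(self, config):
        t = np.linspace(0, 40, 500)
        assert np.all(np.diff(config.thickness_curve()(t)) >= -1e-9)


class TestBScanRendering:
    def test_flat_noise_free_layer_separation(self, config):
        """Two brightest peaks sit round(112 × 1.42 / axial px) pixels apart at 3 h."""
        cfg = noise_free(config, surface_curvature_um_per_mm2=0.0)
        b = render_bscan(cfg, 3.0, 0)
        expected = round(112.0 * 1.42 / b.axial_pixel_um)
        lo, hi = cfg.span_mm()
        cols = [int(x / cfg.lateral_pixel_mm) for x in np.linspace(lo + 0.3, hi - 0.3, 9)]
        for c in cols:
            idx, _ = find_peaks(b.image[:, c], prominence=6.0)
            assert len(idx) == 2
            assert abs((idx[1] - idx[0]) - expected) <= 1

    def test_thickness_fidelity_against_ground_truth(self, config):
        """Noise-free pixel separation equals the truth map within one axial pixel."""
        from seedoct.thickness import pick_boundary_points

        cfg = noise_free(config)
        tc = simulate_timecourse(cfg, n_weight_seeds=1)
        b = tc.bscan(72)  # 12 h
        pick = pick_boundary_points(b)
        truth = tc.truth.thickness_map(12.0, pick.x_mm)
        measured = (pick.lower_um - pick.upper_um) / cfg.coat_ri
        assert np.all(np.abs(measured - truth) <= b.axial_pixel_um)

    def test_no_third_central_peak_before_radicle(self, config):
        from seedoct.reconstruction import average_ascans
        from seedoct.indicators import detect_peaks

        cfg = noise_free(config)
        center = cfg.n_lateral // 2
        before = detect_peaks(average_ascans(render_bscan(cfg, 13.0, 0), center))
        after = detect_peaks(average_ascans(render_bscan(cfg, 14.0, 0), center))
        assert len(before) == 2
        assert len(after) == 3
        # radicle echo stays below the surface peak
        assert after.amplitudes_db[2] < after.surface_amplitude_db

    def test_crack_renders_surface_discontinuity(self, config):
        cfg = noise_free(config)
        b = render_bscan(cfg, 32.0, 0)
        center = cfg.n_lateral // 2
        edge = int((cfg.span_mm()[0] + 0.5) / cfg.lateral_pixel_mm)
        surf_center = np.argmax(b.image[:, center])
        surf_edge = np.argmax(b.image[:, edge])
        # crack displaces the central surface deeper by >= 5 axial pixels
        assert (surf_center - np.argmax(b.image[:, center - 100])) * b.axial_pixel_um \
            >= 5 * b.axial_pixel_um
        assert surf_edge < surf_center

    def test_render_is_deterministic(self, config):
        a = render_bscan(config, 9.0, 123).image
        b = render_bscan(config, 9.0, 123).image
        np.testing.assert_array_equal(a, b)

    def test_time_outside_window_rejected(self, config):
        with pytest.raises(ValueError, match="window"):
            render_bscan(config, 41.0, 0)


class TestWeightModel:
    def test_noise_free_curve_nondecreasing(self, config):
        cfg = replace(config, weight=replace(config.weight, noise_frac=0.0))
        ws = simulate_weight(cfg, "s", 0)
        assert np.all(np.diff(ws.weights_g) >= -1e-12)

    def test_zero_plateau_slope_freezes_phase_two(self, config):
        cfg = replace(config, weight=replace(config.weight, noise_frac=0.0,
                                             plateau_slope_g_per_h=0.0))
        ws = simulate_weight(cfg, "s", 0)
        sel = (ws.times_h > cfg.events.radicle_h) & (ws.times_h < cfg.events.crack_h)
        phase2 = ws.weights_g[sel]
        assert phase2.size >= 2
        np.testing.assert_allclose(phase2, phase2[0])

    def test_cohort_weight_tracks_true_thickness(self, config):
        """Eq.-1 |r| >= 0.95 between cohort-mean weight and the true coat curve."""
        tc = simulate_timecourse(config, n_weight_seeds=10)
        mean_w = np.mean([w.weights_g for w in tc.weights], axis=0)
        thick = config.thickness_curve()(tc.weights[0].times_h)
        paired = align_series(tc.weights[0].times_h, mean_w, tc.weights[0].times_h, thick)
        assert abs(pearson_r(paired).r) >= 0.95

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            WeightSeries("s", [0.0, 0.0, 1.0], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            WeightSeries("s", [0.0, 1.0], [1.0, -1.0])


class TestCameraRendering:
    def test_disc_diameter_recovered_within_one_pixel(self, config):
        from seedoct.morphometry import outline_from_image

        cfg = noise_free(config, events=EventTimes(None, None, None, None))
        img = render_camera_image(cfg, 3.0, 0)
        outline = outline_from_image(img)
        true = cfg.camera.diameter_mm(3.0)
        assert abs(outline.equivalent_diameter_mm - true) <= 1.5 * cfg.camera.pixel_scale_mm

    def test_no_wrinkle_means_smooth_boundary(self, config):
        from seedoct.morphometry import outline_from_image

        cfg = replace(config, events=EventTimes(None, None, None, None))
        outline = outline_from_image(render_camera_image(cfg, 10.0, 0))
        assert outline.roughness < 4e-3

    def test_wrinkled_boundary_rougher(self, config):
        from seedoct.morphometry import outline_from_image

        smooth = outline_from_image(render_camera_image(
            replace(config, events=EventTimes(None, None, None, None)), 10.0, 0))
        wrinkled = outline_from_image(render_camera_image(config, 10.0, 0))
        assert wrinkled.roughness > 3 * smooth.roughness

    def test_seed_mask_is_single_closed_contour(self, config):
        from skimage import measure
        from seedoct.morphometry import segment_seed

        img = render_camera_image(config, 3.0, 0)
        mask = segment_seed(img)
        contours = measure.find_contours(mask.astype(float), 0.5)
        assert len(contours) == 1
        start, end = contours[0][0], contours[0][-1]
        np.testing.assert_allclose(start, end)

    def test_camera_render_deterministic(self, config):
        a = render_camera_image(config, 9.0, 5).pixels
        b = render_camera_image(config, 9.0, 5).pixels
        np.testing.assert_array_equal(a, b)


class TestCohortAndIO:
    def test_cohort_members_are_jittered_but_ordered(self, config):
        cohort = simulate_cohort(config, n_seeds=4)
        radicles = [tc.config.events.radicle_h for tc in cohort]
        assert len(set(radicles)) > 1
        for tc in cohort:
            ev = tc.config.events
            assert ev.wrinkle_h <= ev.cotyledon_h <= ev.radicle_h <= ev.crack_h

    def test_timecourse_reproducible_across_instances(self, config):
        a = simulate_timecourse(config, n_weight_seeds=2)
        b = simulate_timecourse(config, n_weight_seeds=2)
        np.testing.assert_array_equal(a.bscan(30).image, b.bscan(30).image)
        np.testing.assert_array_equal(a.camera(30).pixels, b.camera(30).pixels)
        np.testing.assert_array_equal(a.weights[1].weights_g, b.weights[1].weights_g)

    def test_save_writes_all_artifacts(self, tmp_path, fast_config):
        cfg = replace(fast_config, duration_h=0.5)
        tc = simulate_timecourse(cfg, n_weight_seeds=2)
        paths = tc.save(tmp_path)
        assert paths["oct"].exists()
        df = pd.read_csv(paths["weights"])
        assert list(df.columns) == ["seed_id", "time_h", "weight_g"]
        assert set(df.seed_id) == {"seed1", "seed2"}
        truth = json.loads(paths["ground_truth"].read_text())
        assert len(truth["times_h"]) == len(tc)
        assert (tmp_path / "camera_0000.png").exists()
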