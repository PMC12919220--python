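"""Fly tracking: background model, segmentation, zoning, unit maps, summaries."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from geotax import flytrack as ft
from geotax import synthgen
from geotax.vialdetect import VialLayout

CFG = ft.TrackerConfig()


def grey(shape, value):
    return np.full(shape, value, dtype=np.uint8)


def simple_layout():
    return VialLayout(
        entries=(
            (2, (0.0, 0.0, 100.0, 600.0)),
            (3, (100.0, 0.0, 200.0, 600.0)),
        ),
        frame_size=(200, 600),
    )


class TestComputeBackground:
    def test_static_scene_background_is_the_frame(self):
        frames = [grey((50, 60), 200)] * 5
        bg = ft.compute_background(frames)
        assert np.allclose(bg, 200 / 255)

    def test_moving_dark_dot_removed_by_max_projection(self):
        frames = []
        for x in range(5):
            f = grey((20, 30), 240)
            f[10, 5 * x : 5 * x + 3] = 20
            frames.append(f)
        bg = ft.compute_background(frames)
        assert bg.min() == pytest.approx(240 / 255)

    def test_single_frame_is_its_own_background(self):
        f = grey((10, 10), 123)
        assert np.allclose(ft.compute_background([f]), 123 / 255)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError, match="sizes"):
            ft.compute_background([grey((10, 10), 0), grey((20, 10), 0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ft.compute_background([])


class TestSegmentFlies:
    def test_frame_equal_to_background_yields_nothing(self):
        f = grey((100, 100), 230)
        bg = ft.compute_background([f])
        assert ft.segment_flies(f, bg, CFG) == []

    def test_single_blob_centroid_recovered(self):
        bg_frame = grey((100, 100), 240)
        f = bg_frame.copy()
        f[40:47, 60:67] = 20  # 7x7 blob centred at (63, 43)
        bg = ft.compute_background([bg_frame])
        ((cx, cy),) = ft.segment_flies(f, bg, CFG)
        assert abs(cx - 63.0) <= 1.0 and abs(cy - 43.0) <= 1.0

    def test_blob_below_min_area_excluded(self):
        bg_frame = grey((100, 100), 240)
        f = bg_frame.copy()
        f[10, 10] = 20  # single pixel: below the 4 px^2 floor
        f[60:67, 60:67] = 20
        bg = ft.compute_background([bg_frame])
        assert len(ft.segment_flies(f, bg, CFG)) == 1

    def test_blob_above_max_area_excluded(self):
        bg_frame = grey((100, 100), 240)
        f = bg_frame.copy()
        f[20:70, 20:70] = 20  # 2,500 px^2 blob: merged clump, excluded
        bg = ft.compute_background([bg_frame])
        assert ft.segment_flies(f, bg, CFG) == []


class TestAssignVial:
    def test_containing_box_wins(self):
        assert ft.assign_vial((150.0, 300.0), simple_layout()) == 3

    def test_point_outside_all_boxes_is_none(self):
        assert ft.assign_vial((250.0, 300.0), simple_layout()) is None

    def test_shared_edge_belongs_to_right_box_by_half_open_rule(self):
        # x = 100 is outside [0, 100) but inside [100, 200)
        assert ft.assign_vial((100.0, 300.0), simple_layout()) == 3


class TestClassifyZone:
    box = (0.0, 0.0, 100.0, 600.0)

    def test_vial_bottom_is_low_performer(self):
        assert ft.classify_zone(599.0, self.box, CFG, frame=100) == "LP"

    def test_vial_top_after_guard_is_high_performer(self):
        assert ft.classify_zone(0.0, self.box, CFG, frame=100) == "HP"

    def test_thirds_boundary_arithmetic(self):
        # H = 600, height-from-bottom 250: 200 <= 250 < 400 -> MP
        assert ft.classify_zone(350.0, self.box, CFG, frame=100) == "MP"

    def test_early_frame_guard_suppresses_near_top_centroids(self):
        # within 10% of the vial top during the first 60 frames
        assert ft.classify_zone(30.0, self.box, CFG, frame=10) is None
        assert ft.classify_zone(30.0, self.box, CFG, frame=60) == "HP"

    def test_outside_box_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ft.classify_zone(700.0, self.box, CFG)

    def test_zones_tile_the_vial_exactly(self):
        for y in np.linspace(0.0, 599.0, 97):
            assert ft.classify_zone(float(y), self.box, CFG, frame=100) in (
                "LP", "MP", "HP",
            )


class TestUnitMaps:
    def test_full_image_height_maps_to_holder_height(self):
        assert ft.pixels_to_cm(720) == 17.0

    def test_zero_maps_to_zero(self):
        assert ft.pixels_to_cm(0) == 0.0

    def test_half_height(self):
        assert ft.pixels_to_cm(360) == 8.5

    def test_negative_displacement_rejected(self):
        with pytest.raises(ValueError):
            ft.pixels_to_cm(-1)

    def test_linearity(self):
        rng = np.random.default_rng(2)
        for a, b in rng.uniform(0, 500, size=(20, 2)):
            assert ft.pixels_to_cm(a + b) == pytest.approx(
                ft.pixels_to_cm(a) + ft.pixels_to_cm(b)
            )

    @pytest.mark.parametrize(
        "frame,fps,expected", [(0, 60, 0.0), (900, 60, 15.0), (30, 60, 0.5)]
    )
    def test_frame_to_seconds(self, frame, fps, expected):
        assert ft.frame_to_seconds(frame, fps) == expected

    def test_nonpositive_fps_rejected(self):
        with pytest.raises(ValueError):
            ft.frame_to_seconds(10, 0)


class TestTrackTrim:
    def test_window_limited_to_first_780_frames(self, trim900_records):
        frames_seen = {r.frame for r in trim900_records}
        assert max(frames_seen) == 779
        assert len(frames_seen) == 780

    def test_zero_fly_scene_gives_zero_records(self):
        scene = synthgen.scaled_scene(scale=0.25, n_cycles=1, pause_frames=30,
                                      seed=8)
        kin = [synthgen.FlyKinematics(vial_num=v, n_flies=0) for v in (1, 2)]
        frames, gt = synthgen.render_recording(scene, kin)
        layout = VialLayout(
            entries=tuple((n, tuple(map(float, b[1:])))
                          for n, *b in [(n, x1, y1, x2, y2)
                                        for n, x1, y1, x2, y2 in gt.boxes]),
            frame_size=scene.image_size,
        )
        cfg = replace(CFG, image_height_px=float(scene.image_size[1]),
                      frames_per_trim=30)
        assert ft.track_trim(frames[5:35], layout, cfg) == []

    def test_separable_flies_counted_within_one(self):
        # full-scale vial, 5 flies climbing without stalls at distinct speeds
        scene = synthgen.scaled_scene(scale=1.0, n_cycles=1, pause_frames=310,
                                      seed=12)
        kin = [synthgen.FlyKinematics(vial_num=1, n_flies=5,
                                      climb_speed_cm_s=1.5, speed_sd=0.6)]
        frames, gt = synthgen.render_recording(scene, kin)
        layout = VialLayout(
            entries=tuple(
                (n, (float(x1), float(y1), float(x2), float(y2)))
                for n, x1, y1, x2, y2 in gt.boxes
            ),
            frame_size=scene.image_size,
        )
        cfg = replace(CFG, frames_per_trim=300)
        records = ft.track_trim(frames[5:305], layout, cfg)
        df = ft.records_to_frame(records)
        counts = df[df.vial_num == 1].groupby("frame").size()
        counts = counts.reindex(range(300), fill_value=0)
        ok = ((counts >= 4) & (counts <= 6)).mean()
        assert ok >= 0.90

    def test_recovery_close_to_ground_truth(self, trim900, trim900_records):
        trim, layout, cfg, gt = trim900
        df = ft.records_to_frame(trim900_records)
        traj = gt.trajectories
        traj = traj[traj.frame >= synthgen.TAP_BURST_FRAMES].copy()
        traj["tf"] = traj.frame - synthgen.TAP_BURST_FRAMES
        errs = []
        for (f, v), sub in df.groupby(["frame", "vial_num"]):
            gtsub = traj[(traj.tf == f) & (traj.vial_num == v)]
            for r in sub.itertuples():
                d = np.sqrt((gtsub.x - r.x) ** 2 + (gtsub.y - r.y) ** 2).min()
                errs.append(d)
        rms = float(np.sqrt(np.mean(np.square(errs))))
        assert rms <= 2.0

    def test_mean_height_series_nondecreasing_for_pure_climbers(self):
        # noise-free scene, one strict climber per vial: the recovered mean
        # height series must never decrease
        scene = synthgen.scaled_scene(scale=0.25, n_cycles=1,
                                      pause_frames=400, noise_sd=0.0, seed=6)
        kin = [synthgen.FlyKinematics(vial_num=v, n_flies=1,
                                      climb_speed_cm_s=0.8) for v in (1, 7)]
        frames, gt = synthgen.render_recording(scene, kin)
        layout = VialLayout(
            entries=tuple(
                (n, (float(x1), float(y1), float(x2), float(y2)))
                for n, x1, y1, x2, y2 in gt.boxes
            ),
            frame_size=scene.image_size,
        )
        cfg = replace(CFG, image_height_px=float(scene.image_size[1]),
                      frames_per_trim=390)
        records = ft.track_trim(frames[5:], layout, cfg)
        summary = ft.summarize_trim(records, layout, cfg)
        for vial in (1, 7):
            series = summary.height_cm[vial].dropna().to_numpy()
            assert np.all(np.diff(series) >= -1e-9)


class TestSummaries:
    def make_records(self, frames, vial=2, y=599.0):
        return [
            ft.CentroidRecord(trim=1, frame=f, vial_num=vial, x=50.0, y=y,
                              zone="LP")
            for f in frames
        ]

    def test_26_time_points_for_780_frames_at_step_30(self, trim900,
                                                      trim900_records):
        _, layout, cfg, _ = trim900
        s = ft.summarize_trim(trim900_records, layout, cfg)
        assert len(s.height_cm.index) == 26
        assert s.height_cm.index[1] - s.height_cm.index[0] == pytest.approx(0.5)

    def test_fly_at_bottom_scores_lp_100_height_0(self):
        layout = simple_layout()
        records = self.make_records(range(0, 780, 30))
        s = ft.summarize_trim(records, layout, CFG)
        assert np.allclose(s.pct_lp[2].dropna(), 100.0)
        assert np.allclose(s.height_cm[2].dropna(), 17.0 * 1.0 / 720.0,
                           atol=1e-6)

    def test_zone_percentages_sum_to_100(self, trim900, trim900_records):
        _, layout, cfg, _ = trim900
        s = ft.summarize_trim(trim900_records, layout, cfg)
        total = s.pct_lp + s.pct_mp + s.pct_hp
        assert np.allclose(total.dropna(how="all").to_numpy(dtype=float),
                           100.0, equal_nan=True)


class TestAggregateTrims:
    def summary_with_value(self, value, trim):
        idx = pd.Index([0.0, 0.5], name="time_s")
        df = pd.DataFrame({2: [value, value]}, index=idx, dtype=float)
        return ft.TrimSummary(trim=trim, height_cm=df, pct_lp=df.copy(),
                              pct_mp=df.copy(), pct_hp=df.copy())

    def test_identical_trims_have_zero_sem(self):
        agg = ft.aggregate_trims([self.summary_with_value(5.0, k)
                                  for k in range(1, 5)])
        assert np.allclose(agg.sem["position"].to_numpy(), 0.0)
        assert np.allclose(agg.mean["position"].to_numpy(), 5.0)

    def test_mean_and_sem_hand_arithmetic(self):
        agg = ft.aggregate_trims(
            [self.summary_with_value(v, k)
             for k, v in enumerate([1.0, 2.0, 3.0, 4.0], start=1)]
        )
        assert np.allclose(agg.mean["position"].to_numpy(), 2.5)
        assert np.allclose(agg.sem["position"].to_numpy(), 0.6455, atol=1e-4)

    def test_single_trim_sem_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            agg = ft.aggregate_trims([self.summary_with_value(3.0, 1)])
        assert np.allclose(agg.sem["position"].to_numpy(), 0.0)
        assert "single trim" in caplog.text

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ft.aggregate_trims([])

    def test_summary_csv_roundtrip(self, tmp_path):
        agg = ft.aggregate_trims(
            [self.summary_with_value(v, k)
             for k, v in enumerate([1.0, 2.0], start=1)]
        )
        ft.write_summary_csvs(agg, tmp_path)
        back = ft.read_summary_csv(tmp_path / "position.csv")
        assert np.allclose(back["Vial_2"].to_numpy(), 1.5)
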