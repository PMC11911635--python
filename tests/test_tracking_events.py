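import numpy as np
import pytest

from conftest import make_trace
from phenocage import (
    SegmentationConfig,
    detect_freezing,
    distance_to_first_entry,
    segment_events,
    simulate_homecage_trace,
    zone_metrics,
)
from phenocage.geometry import (
    DiscZone,
    RectZone,
    open_field_arena,
    phenotyper_arena,
    quadrant_partition,
    water_maze_arena,
)
from phenocage.tracking_events import KeypointTrace, QCError, score_interactions


class TestSegmentation:
    def test_constant_position_outside_shelter_is_one_arrest(self, homecage_arena):
        n = 300  # 60 s at 5/s
        trace = make_trace(np.full(n, 20.0), np.full(n, 10.0), arena=homecage_arena)
        ev = segment_events(trace)
        arrests = ev.of_kind("arrest")
        assert len(arrests) == 1
        assert arrests.loc[0, "start"] == 0.0
        assert arrests.loc[0, "end"] == pytest.approx(60.0)
        assert len(ev.of_kind("movement")) == 0

    def test_whole_trace_in_shelter(self, homecage_arena):
        sx, sy = homecage_arena.zones["shelter"].center
        trace = make_trace(np.full(500, sx), np.full(500, sy), arena=homecage_arena)
        ev = segment_events(trace)
        visits = ev.of_kind("shelter_visit")
        assert len(visits) == 1
        assert visits.loc[0, "end"] - visits.loc[0, "start"] == pytest.approx(100.0)
        assert len(ev.of_kind("movement")) == 0 and len(ev.of_kind("arrest")) == 0

    def test_generator_ground_truth_recovered(self, day_spec, seg_cfg):
        """Jitter-free generator output is reconstructed exactly."""
        trace, truth = simulate_homecage_trace(day_spec)
        ev = segment_events(trace, seg_cfg)
        one_frame = 1.0 / trace.sample_rate
        for kind in ("movement", "arrest", "shelter_visit", "activity_bout"):
            t = truth.of_kind(kind).sort_values("start").reset_index(drop=True)
            s = ev.of_kind(kind).sort_values("start").reset_index(drop=True)
            assert len(t) == len(s), kind
            assert np.abs(t["start"] - s["start"]).max() <= one_frame + 1e-9
            assert np.abs(t["end"] - s["end"]).max() <= one_frame + 1e-9
        np.testing.assert_allclose(
            truth.of_kind("movement")["distance"],
            ev.of_kind("movement")["distance"],
            rtol=1e-9,
        )

    def test_time_conservation(self, day_spec):
        trace, _ = simulate_homecage_trace(day_spec)
        ev = segment_events(trace)
        shelter = ev.total_time("shelter_visit")
        moving = ev.total_time("movement")
        arrested = ev.total_time("arrest")
        assert shelter + moving + arrested == pytest.approx(trace.duration)

    def test_movements_merged_across_short_gaps(self, homecage_arena):
        # 2 s moving, 0.4 s pause (< merge_gap 0.5), 2 s moving, at 5/s
        rate = 5.0
        step = 1.0  # 5 cm/s > v_move
        xs = [20.0]
        for seg in ([step] * 10, [0.0] * 2, [step] * 10, [0.0] * 10):
            for d in seg:
                xs.append(min(xs[-1] + d, 28.0) if d else xs[-1])
        xs = np.asarray(xs)
        # keep the path inside the box by folding
        xs = 2.0 + np.abs((xs - 2.0) % 52.0 - 26.0)
        trace = make_trace(xs, np.full(len(xs), 5.0), sample_rate=rate,
                           arena=homecage_arena)
        ev = segment_events(trace)
        assert len(ev.of_kind("movement")) == 1

    def test_qc_error_on_excess_missing(self, homecage_arena):
        x = np.full(100, 15.0)
        x[:40] = np.nan
        trace = make_trace(x, np.full(100, 15.0), arena=homecage_arena)
        with pytest.raises(QCError):
            segment_events(trace)


class TestFreezing:
    def test_constant_position_fully_frozen(self):
        trace = make_trace(np.full(3000, 10.0), np.full(3000, 10.0))  # 600 s at 5/s
        _, bins = detect_freezing(trace)
        assert len(bins) == 10
        assert (bins["percent_frozen"] == 100.0).all()

    def test_steady_motion_never_frozen(self):
        n = 3000
        x = np.arange(n) * 1.0  # 5 cm/s at 5/s > v_freeze
        trace = make_trace(x, np.zeros(n))
        _, bins = detect_freezing(trace)
        assert (bins["percent_frozen"] == 0.0).all()

    def test_half_frozen_alternation(self):
        # 30 s still / 30 s moving blocks, 600 s at 5/s
        rate = 5.0
        blocks = []
        for i in range(10):
            blocks += [0.0] * 150 + [1.0] * 150
        steps = np.asarray(blocks)
        x = np.concatenate([[0.0], np.cumsum(steps)])[:-1]
        trace = make_trace(x, np.zeros(len(x)), sample_rate=rate)
        _, bins = detect_freezing(trace)
        assert np.allclose(bins["percent_frozen"], 50.0, atol=1.0)

    def test_partial_final_bin_reported(self):
        trace = make_trace(np.full(450, 1.0), np.full(450, 1.0))  # 90 s at 5/s
        _, bins = detect_freezing(trace)
        assert len(bins) == 2
        assert bins.loc[1, "bin_duration"] == pytest.approx(30.0)

    def test_too_short_trace_rejected(self):
        trace = make_trace(np.zeros(10), np.zeros(10))
        with pytest.raises(ValueError):
            detect_freezing(trace)


class TestZoneMetrics:
    def test_path_inside_inner_zone(self):
        arena = open_field_arena()
        rng = np.random.default_rng(0)
        x = 25.0 + np.cumsum(rng.uniform(-0.5, 0.5, 500))
        y = 25.0 + np.cumsum(rng.uniform(-0.5, 0.5, 500))
        x = np.clip(x, 10, 40)
        y = np.clip(y, 10, 40)
        trace = make_trace(x, y, arena=arena)
        zones = {"inner": arena.zone("inner")}
        m = zone_metrics(trace, zones)
        assert m.loc["inner", "time_fraction"] == 1.0
        assert m.loc["inner", "relative_distance"] == pytest.approx(1.0)

    def test_quadrant_relative_distances_sum_to_one(self):
        arena = water_maze_arena()
        rng = np.random.default_rng(3)
        ang = np.cumsum(rng.normal(0, 0.4, 2000))
        r = 30 + 20 * np.sin(np.linspace(0, 8, 2000))
        trace = make_trace(r * np.cos(ang), r * np.sin(ang), arena=arena)
        quads = {q: arena.zone(q) for q in ("NW", "NE", "SE", "SW")}
        m = zone_metrics(trace, quads)
        assert m["relative_distance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert m["time_fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_per_sample_oracle(self):
        """Zone distance equals a brute-force per-sample assignment."""
        arena = water_maze_arena()
        rng = np.random.default_rng(7)
        ang = np.cumsum(rng.normal(0, 0.3, 800))
        x = 25 * np.cos(ang)
        y = 25 * np.sin(ang)
        trace = make_trace(x, y, arena=arena)
        quads = quadrant_partition(0.0, 0.0, 60.0)
        m = zone_metrics(trace, quads)
        steps = np.hypot(np.diff(x), np.diff(y))
        for q, z in quads.items():
            inside = np.asarray(z.contains(x, y))
            assert m.loc[q, "distance_cm"] == pytest.approx(
                steps[inside[:-1]].sum()
            )

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(0, 0.3, 400)) + 25
        y = np.cumsum(rng.normal(0, 0.3, 400)) + 25
        z = RectZone(20, 20, 30, 30)
        m1 = zone_metrics(make_trace(x, y), {"z": z})
        m2 = zone_metrics(make_trace(x + 7, y - 3), {"z": z.translated(7, -3)})
        for col in ("time_s", "distance_cm", "entries"):
            assert m1.loc["z", col] == pytest.approx(m2.loc["z", col])

    def test_zone_outside_arena_rejected(self):
        arena = open_field_arena()
        trace = make_trace(np.full(50, 25.0), np.full(50, 25.0), arena=arena)
        with pytest.raises(ValueError):
            zone_metrics(trace, {"far": RectZone(100, 100, 110, 110)})


class TestDistanceToFirstEntry:
    def test_straight_line_approach(self):
        x = np.linspace(0, 41, 83)  # 0.5 cm steps toward a target at 40
        trace = make_trace(x, np.zeros_like(x))
        d, reached = distance_to_first_entry(trace, DiscZone(41.0, 0.0, 1.0))
        assert reached
        assert d == pytest.approx(40.0, abs=0.5)

    def test_start_inside_target(self):
        trace = make_trace(np.zeros(10), np.zeros(10))
        d, reached = distance_to_first_entry(trace, DiscZone(0, 0, 2))
        assert d == 0.0 and reached

    def test_never_reached_returns_total_length(self):
        rng = np.random.default_rng(5)
        x = np.cumsum(rng.normal(0, 0.2, 300))
        y = np.cumsum(rng.normal(0, 0.2, 300))
        trace = make_trace(x, y)
        d, reached = distance_to_first_entry(trace, DiscZone(500, 500, 1))
        assert not reached
        assert d == pytest.approx(np.hypot(np.diff(x), np.diff(y)).sum())

    def test_matches_cumsum_oracle(self):
        rng = np.random.default_rng(9)
        x = np.cumsum(rng.normal(0, 1.0, 500))
        y = np.cumsum(rng.normal(0, 1.0, 500))
        trace = make_trace(x, y)
        target = DiscZone(10.0, 5.0, 3.0)
        inside = np.asarray(target.contains(x, y))
        steps = np.hypot(np.diff(x), np.diff(y))
        k = int(np.flatnonzero(inside)[0])
        d, reached = distance_to_first_entry(trace, target)
        assert reached
        assert d == pytest.approx(steps[:k].sum())


class TestInteractions:
    def _kp(self, nose, conf=None, rate=20.0):
        n = len(nose)
        conf = np.ones(n) if conf is None else conf
        back = nose + np.array([3.0, 0.0])
        return KeypointTrace(
            coords={"nose": nose, "shoulders": back, "back": back},
            confidence={"nose": conf, "shoulders": np.ones(n), "back": np.ones(n)},
            sample_rate=rate,
        )

    def test_known_frame_count(self):
        target = {"obj": DiscZone(0.0, 0.0, 2.0)}
        F = 137
        nose = np.tile([50.0, 50.0], (400, 1))
        nose[:F] = (0.0, 0.0)
        out = score_interactions(self._kp(nose), target)
        assert out.seconds["obj"] == pytest.approx(F / 20.0)

    def test_low_confidence_frames_excluded(self):
        target = {"obj": DiscZone(0.0, 0.0, 2.0)}
        nose = np.tile([0.0, 0.0], (100, 1))
        conf = np.ones(100)
        conf[:50] = 0.1
        out = score_interactions(self._kp(nose, conf), target)
        assert out.seconds["obj"] == pytest.approx(50 / 20.0)
        assert out.valid_fraction == 0.5

    def test_all_low_confidence_rejected(self):
        target = {"obj": DiscZone(0.0, 0.0, 2.0)}
        nose = np.tile([0.0, 0.0], (100, 1))
        with pytest.raises(QCError):
            score_interactions(self._kp(nose, np.full(100, 0.2)), target)

    def test_proximity_radius_beyond_boundary(self):
        cfg = SegmentationConfig()
        target = {"obj": DiscZone(0.0, 0.0, 2.0)}
        nose = np.tile([2.0 + cfg.proximity_radius - 0.1, 0.0], (10, 1))
        out = score_interactions(self._kp(nose), target, cfg)
        assert out.seconds["obj"] == pytest.approx(0.5)
        nose2 = np.tile([2.0 + cfg.proximity_radius + 0.1, 0.0], (10, 1))
        assert score_interactions(self._kp(nose2), target, cfg).seconds["obj"] == 0.0
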