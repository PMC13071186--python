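import numpy as np
import pytest

import arenawalk as aw
from arenawalk.errors import InvalidParameterError
from arenawalk.features import (FEATURE_COLUMNS, TrajectoryRecord, body_angles,
                                build_feature_table, extract_features,
                                kinematics, turning, wall_interactions,
                                zone_times)
from arenawalk.tracking import Trajectory, TrackingConfig


def make_traj(parts, fps=60.0, px_to_mm=0.055):
    return Trajectory.from_parts(
        {k: np.asarray(v, float) for k, v in parts.items()}, fps, px_to_mm)


class TestKinematics:
    def test_stationary_track(self, track_config):
        traj = make_traj({"body_centroid": np.tile([100.0, 100.0], (600, 1))},
                         px_to_mm=0.11)
        k = kinematics(traj, track_config)
        assert k.distance == 0.0
        assert k.stop_time == pytest.approx(10.0)
        assert k.max_speed == 0.0

    def test_straight_path_speed_closed_form(self):
        """1 px/frame at 60 fps and 0.055 mm/px is 3.3 mm/s."""
        cfg = TrackingConfig(fps=60.0, px_to_mm=0.055)
        xy = np.stack([np.arange(300.0), np.zeros(300)], 1)
        k = kinematics(make_traj({"body_centroid": xy}), cfg)
        assert k.mean_speed == pytest.approx(3.3)
        assert k.max_speed == pytest.approx(3.3)
        assert k.mean_abs_acceleration == pytest.approx(0.0, abs=1e-9)

    def test_circular_path_distance_matches_arc_length(self):
        cfg = TrackingConfig(fps=60.0, px_to_mm=0.055)
        n, r, om = 2000, 100.0, 0.02
        ang = om * np.arange(n)
        xy = np.stack([500 + r * np.cos(ang), 300 + r * np.sin(ang)], 1)
        k = kinematics(make_traj({"body_centroid": xy}), cfg)
        analytic = r * om * (n - 1) * 0.055
        assert k.distance == pytest.approx(analytic, rel=0.005)

    def test_single_frame_rejected(self, track_config):
        with pytest.raises(InvalidParameterError):
            kinematics(make_traj({"body_centroid": [[0.0, 0.0]]}), track_config)

    def test_unit_coherence_px_to_mm_scaling(self, track_config):
        """Doubling the mm-per-px factor doubles distances and speeds but
        leaves times unchanged."""
        rng = np.random.default_rng(5)
        xy = np.cumsum(rng.normal(0, 2, size=(400, 2)), 0) + 400
        k1 = kinematics(make_traj({"body_centroid": xy}, px_to_mm=0.11),
                        track_config)
        k2 = kinematics(make_traj({"body_centroid": xy}, px_to_mm=0.22),
                        track_config)
        assert k2.distance == pytest.approx(2 * k1.distance)
        assert k2.mean_speed == pytest.approx(2 * k1.mean_speed)


class TestZones:
    def test_orbit_outside_inner_radius_is_all_outer(self, arena):
        ang = np.linspace(0, 4 * np.pi, 600)
        r = 0.9 * arena.radius
        xy = np.stack([arena.centre[0] + r * np.cos(ang),
                       arena.centre[1] + r * np.sin(ang)], 1)
        inner, outer = zone_times(make_traj({"body_centroid": xy}), arena)
        assert inner == 0.0
        assert outer == pytest.approx(600 / 60.0)

    def test_sitting_at_centre_is_all_inner(self, arena):
        xy = np.tile(arena.centre, (120, 1))
        inner, outer = zone_times(make_traj({"body_centroid": xy}), arena)
        assert outer == 0.0 and inner == pytest.approx(2.0)

    def test_scripted_half_and_half_split(self, arena):
        inside = np.tile(arena.centre, (150, 1))
        outside = np.tile([arena.centre[0] + 0.8 * arena.radius,
                           arena.centre[1]], (150, 1))
        xy = np.vstack([inside, outside])
        inner, outer = zone_times(make_traj({"body_centroid": xy}), arena)
        assert inner == outer == pytest.approx(2.5)

    def test_boundary_counts_as_inner(self, arena):
        xy = np.tile([arena.centre[0] + arena.inner_radius, arena.centre[1]],
                     (60, 1))
        inner, outer = zone_times(make_traj({"body_centroid": xy}), arena)
        assert inner == pytest.approx(1.0) and outer == 0.0

    def test_times_sum_to_duration(self, arena, control_truth):
        traj = make_traj({"body_centroid": control_truth.centroid}, px_to_mm=0.11)
        inner, outer = zone_times(traj, arena)
        assert inner + outer == pytest.approx(control_truth.n_frames / 60.0)


class TestWallInteractions:
    def test_path_far_from_wall_has_no_contact(self, arena):
        xy = np.tile([arena.centre[0] + 0.5 * arena.radius, arena.centre[1]],
                     (100, 1))
        w = wall_interactions(xy, arena, fps=60.0)
        assert w.n_events == 0 and w.contact_time == 0.0

    def test_scripted_five_entries_count_five_events(self, arena):
        near = [arena.centre[0] + arena.radius - 2.0, arena.centre[1]]
        far = [arena.centre[0], arena.centre[1]]
        xy = []
        for _ in range(5):
            xy += [far] * 10 + [near] * 4       # 4-frame dwell >= debounce
        xy += [far] * 10
        w = wall_interactions(np.array(xy), arena, fps=60.0)
        assert w.n_events == 5
        assert w.contact_time == pytest.approx(20 / 60.0)

    def test_permanent_contact_is_one_event_full_duration(self, arena):
        xy = np.tile([arena.centre[0] + arena.radius - 1.0, arena.centre[1]],
                     (90, 1))
        w = wall_interactions(xy, arena, fps=60.0)
        assert w.n_events == 1
        assert w.contact_time == pytest.approx(1.5)

    def test_single_frame_jitter_is_debounced(self, arena):
        near = [arena.centre[0] + arena.radius - 2.0, arena.centre[1]]
        far = [arena.centre[0], arena.centre[1]]
        xy = np.array([far] * 5 + [near] + [far] * 5)
        w = wall_interactions(xy, arena, fps=60.0, min_dwell=2)
        assert w.n_events == 0
        assert w.contact_time == pytest.approx(1 / 60.0)


class TestBodyAngles:
    def test_cardinal_directions(self):
        head = np.array([[1.0, 0.0], [0.0, -1.0]])
        back = np.zeros((2, 2))
        ang, valid = body_angles(head, back)
        assert ang[0] == pytest.approx(0.0)          # head right of back
        assert ang[1] == pytest.approx(np.pi / 2)    # head above (arena coords)
        assert valid.all()

    def test_matches_quadrant_resolved_arctangent(self):
        """Random geometry agrees with a brute-force quadrant-resolved
        arctangent oracle."""
        rng = np.random.default_rng(8)
        head = rng.normal(size=(200, 2)) * 50 + 300
        back = rng.normal(size=(200, 2)) * 50 + 300
        ang, valid = body_angles(head, back)
        for i in range(200):
            dx = head[i, 0] - back[i, 0]
            dy = -(head[i, 1] - back[i, 1])
            if dx == 0 and dy == 0:
                continue
            ref = np.arctan(abs(dy) / abs(dx)) if dx != 0 else np.pi / 2
            if dx < 0:
                ref = np.pi - ref
            if dy < 0:
                ref = -ref
            assert ang[i] == pytest.approx(ref, abs=1e-12)
        assert (np.abs(ang) <= np.pi).all()

    def test_coincident_points_carry_previous_angle(self):
        head = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 1.0]])
        back = np.zeros((3, 2))
        ang, valid = body_angles(head, back)
        assert not valid[1]
        assert ang[1] == ang[0]


class TestTurning:
    def test_constant_heading_no_turns(self):
        t = turning(np.full(50, 0.3))
        assert t.left_turns == t.right_turns == 0
        assert t.cumulative_rotation == 0.0

    def test_three_ccw_rotations(self):
        angles = np.linspace(0, 6 * np.pi, 700)      # 3 full CCW loops
        t = turning(angles)
        assert t.left_turns == 3 and t.right_turns == 0
        assert t.cumulative_rotation == pytest.approx(6 * np.pi)

    def test_reversal_swaps_left_and_right(self):
        rng = np.random.default_rng(4)
        angles = np.cumsum(rng.normal(0, 0.3, 400))
        fwd = turning(angles)
        rev = turning(angles[::-1])
        assert fwd.left_turns == rev.right_turns
        assert fwd.right_turns == rev.left_turns
        assert fwd.cumulative_rotation == pytest.approx(-rev.cumulative_rotation)

    def test_rotation_consistency_with_turn_counts(self):
        rng = np.random.default_rng(9)
        angles = np.cumsum(rng.normal(0.05, 0.2, 1000))
        t = turning(angles)
        assert t.left_turns - t.right_turns == pytest.approx(
            t.cumulative_rotation / (2 * np.pi), abs=2.0)


class TestFeatureTable:
    def test_one_row_per_individual_with_labels(self, cohort_table):
        assert len(cohort_table) == 192
        assert set(cohort_table["group"]) == {"control", "lc10", "lc30"}
        assert set(cohort_table["sex"]) == {"male", "female"}
        for col in FEATURE_COLUMNS:
            assert col in cohort_table.columns

    def test_control_covers_more_distance_than_treated(self, cohort_table):
        means = cohort_table.groupby("group")["distance"].mean()
        assert means["control"] > means["lc10"] > means["lc30"]

    def test_zone_times_sum_to_duration(self, cohort_table):
        total = cohort_table["inner_time"] + cohort_table["outer_time"]
        assert np.allclose(total, 30.0)
        assert (cohort_table["stop_time"] <= 30.0 + 1e-9).all()
        assert (cohort_table["wall_contact_time"] <= 30.0 + 1e-9).all()

    def test_stationary_individual_is_all_stop_time(self, arena, track_config):
        preset = aw.MotionPreset("still", mean_speed=1.0, turn_kappa=5.0,
                                 stop_rate=1.0, go_rate=0.0, wall_bias=0.0)
        truth = aw.simulate_trajectory(preset, 300, 60.0, arena, seed=3)
        traj = Trajectory.from_parts(truth.part_positions(), 60.0, 0.11)
        feats = extract_features(traj, arena, track_config)
        assert feats["distance"] == 0.0
        assert feats["stop_time"] == pytest.approx(5.0)
        assert feats["inner_time"] + feats["outer_time"] == pytest.approx(5.0)
        assert feats["left_turns"] == feats["right_turns"] == 0

    def test_missing_parts_flag_incomplete(self, arena, track_config):
        traj = make_traj({"body_centroid": np.tile(arena.centre, (60, 1))},
                         px_to_mm=0.11)
        feats = extract_features(traj, arena, track_config)
        assert feats["incomplete"]
        assert np.isnan(feats["thigmo_left"])
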