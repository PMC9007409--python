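import math

import numpy as np
import pytest
from shapely.geometry import LineString, box

from reachbias import classify as cf
from reachbias import kinematics as km
from reachbias import synthetic as syn
from reachbias.config import experiment_config

from conftest import line_trajectory


def brute_force_commit(traj, targets, radius, onset_ms, end_ms):
    """Independent per-sample oracle: recompute heading and window
    membership sample by sample with plain trigonometry."""
    t = traj[:, 0]
    for i in range(len(traj)):
        if t[i] < onset_ms or t[i] > end_ms:
            continue
        lo, hi = max(i - 2, 0), min(i + 2, len(traj) - 1)
        vx = (traj[hi, 1] - traj[lo, 1]) / (t[hi] - t[lo])
        vy = (traj[hi, 2] - traj[lo, 2]) / (t[hi] - t[lo])
        if vx == 0 and vy == 0:
            continue
        h = math.degrees(math.atan2(vx, vy))
        for cx, cy in targets:
            dx, dy = cx - traj[i, 1], cy - traj[i, 2]
            d = math.hypot(dx, dy)
            if d == 0:
                continue
            if d <= radius:
                return t[i]
            half = math.degrees(math.asin(min(radius / d, 1.0)))
            dev = abs((h - math.degrees(math.atan2(dx, dy)) + 180) % 360 - 180)
            if dev <= half:
                return t[i]
    return None


class TestCommitTime:
    def test_straight_at_target_commits_at_onset(self, cfg1):
        traj = line_trajectory(22.5, dt_ms=10.0)
        onset = km.detect_onset(traj, cfg1.onset_velocity_threshold)
        t_commit = cf.find_commit_time(traj, cfg1.target_positions(), cfg1)
        assert t_commit == onset

    def test_midline_path_never_commits(self, cfg1):
        traj = line_trajectory(0.0, distance_cm=19.0)
        assert cf.find_commit_time(traj, cfg1.target_positions(), cfg1) is None

    def test_random_trajectories_match_brute_force_oracle(self, cfg1):
        rng = np.random.default_rng(12345)
        targets = cfg1.target_positions()
        for _ in range(100):
            # piecewise-heading toy path: hold, then 2 segments of random heading
            dt = 10.0
            n1, n2 = rng.integers(10, 30), rng.integers(10, 30)
            h1, h2 = rng.uniform(-60, 60, size=2)
            speeds = rng.uniform(0.01, 0.05, size=2)  # cm/ms
            headings = np.concatenate([np.full(n1, h1), np.full(n2, h2)])
            v = np.concatenate([np.full(n1, speeds[0]), np.full(n2, speeds[1])])
            steps = np.column_stack([np.sin(np.deg2rad(headings)), np.cos(np.deg2rad(headings))]) * (v * dt)[:, None]
            xy = np.vstack([np.zeros((5, 2)), np.cumsum(steps, axis=0)])
            t = np.arange(len(xy)) * dt
            traj = np.column_stack([t, xy])
            onset = km.detect_onset(traj, cfg1.onset_velocity_threshold)
            end = km.end_of_motion(traj, cfg1.onset_velocity_threshold)
            got = cf.find_commit_time(traj, targets, cfg1, onset_ms=onset, end_ms=end)
            want = brute_force_commit(traj, targets, cfg1.capture_radius, onset, end)
            assert got == want

    def test_two_phase_turn_commits_at_constructed_sample(self, cfg1):
        # straight up the midline, then turn exactly toward the right target
        dt = 10.0
        n1 = 20
        xy = [(0.0, 0.0)] * 3
        x = y = 0.0
        for _ in range(n1):
            y += 0.3
            xy.append((x, y))
        target = cfg1.target_positions()[1]
        for _ in range(40):
            dx, dy = target[0] - x, target[1] - y
            d = math.hypot(dx, dy)
            x += 0.35 * dx / d
            y += 0.35 * dy / d
            xy.append((x, y))
        traj = np.column_stack([np.arange(len(xy)) * dt, np.asarray(xy)])
        onset = km.detect_onset(traj, cfg1.onset_velocity_threshold)
        end = km.end_of_motion(traj, cfg1.onset_velocity_threshold)
        got = cf.find_commit_time(traj, cfg1.target_positions(), cfg1, onset_ms=onset, end_ms=end)
        want = brute_force_commit(traj, cfg1.target_positions(), cfg1.capture_radius, onset, end)
        assert got == want
        assert got is not None and got > (3 + n1) * dt - 3 * dt


class TestTemporalRule:
    @pytest.mark.parametrize("t_commit,t_reveal,expected", [
        (300.0, 400.0, "direct"),
        (470.0, 400.0, "intermediate"),   # not strictly before 460
        (460.0, 400.0, "intermediate"),   # boundary: equality is intermediate
        (459.9, 400.0, "direct"),
        (None, 400.0, "intermediate"),
    ])
    def test_rule(self, t_commit, t_reveal, expected):
        assert cf.classify_temporal(t_commit, t_reveal, delay_ms=60.0) == expected


class TestGeometric:
    def test_path_through_rectangle_is_intermediate(self, cfg3):
        traj = line_trajectory(0.0, distance_cm=15.0)
        assert cf.classify_geometric(traj, cfg3) == "intermediate"

    def test_path_to_near_target_is_direct(self, cfg3):
        traj = line_trajectory(45.0, distance_cm=11.0)
        assert cf.classify_geometric(traj, cfg3) == "direct"

    def test_requires_five_target_layout(self, cfg1):
        with pytest.raises(ValueError):
            cf.classify_geometric(line_trajectory(0.0), cfg1)

    def test_random_paths_match_shapely_oracle(self, cfg3):
        rng = np.random.default_rng(999)
        rect = cfg3.rectangle
        rect_poly = box(-rect.x_half_cm, rect.y_center_cm - rect.y_half_cm,
                        rect.x_half_cm, rect.y_center_cm + rect.y_half_cm)
        for _ in range(100):
            angle = rng.uniform(-75, 75)
            traj = line_trajectory(angle, distance_cm=rng.uniform(8, 16))
            path = LineString(traj[:, 1:3])
            # for straight rays from the origin the rectangle (when hit) is
            # always reached before either near target, so interception of
            # the box alone decides the label
            expected = "intermediate" if path.intersects(rect_poly) else "direct"
            assert cf.classify_geometric(traj, cfg3) == expected

    def test_agrees_with_temporal_on_simulated_trials(self, cfg3):
        profile = syn.ParticipantProfile(motor_sd_deg=1.0, p_intermediate=0.5)
        design = syn.exp3_design(n_trials_per_block=4, near_far_ratios=(1.0,))
        session = syn.simulate_session(profile, design, cfg3, seed=21, participant_id="P0")
        agree, total = 0, 0
        for trial, traj in session.iter_trials():
            summary = km.summarize(traj, cfg3)
            t_commit = cf.find_commit_time(
                traj, cfg3.target_positions(), cfg3,
                onset_ms=summary.onset_ms, end_ms=summary.end_of_motion_ms,
            )
            temporal = cf.classify_temporal(t_commit, trial["t_reveal"], cfg3.perception_delay_ms)
            geometric = cf.classify_geometric(traj, cfg3)
            agree += temporal == geometric
            total += 1
        assert agree / total >= 0.95


class TestOutcome:
    def test_through_correct_center_is_hit(self, cfg1):
        correct, incorrect = cfg1.target_positions()[1], cfg1.target_positions()[0]
        traj = line_trajectory(22.5, distance_cm=22.0)
        assert cf.classify_outcome(traj, correct, incorrect, cfg1) == "hit"

    def test_through_incorrect_center_is_choice_error(self, cfg1):
        correct, incorrect = cfg1.target_positions()[1], cfg1.target_positions()[0]
        traj = line_trajectory(-22.5, distance_cm=22.0)
        assert cf.classify_outcome(traj, correct, incorrect, cfg1) == "choice_error"

    def test_hand_computed_miss_distances_give_motor_error(self, cfg1):
        # vertical line at x = 5.65: passes 2.0 cm from a target at (7.65, 18.48)
        # and ~13.3 cm from the mirrored target -> miss > 1.5 cm capture radius
        correct = np.array([7.65, 18.48])
        incorrect = np.array([-7.65, 18.48])
        t = np.arange(0, 610, 10.0)
        y = np.concatenate([np.zeros(10), np.linspace(0, 25, 51)])
        traj = np.column_stack([t, np.full_like(t, 5.65), y])
        assert cf.classify_outcome(traj, correct, incorrect, cfg1) == "motor_error"

    def test_partition_exhaustive_on_simulated_session(self, cfg1, small_session):
        classified = cf.classify_session(small_session, cfg1)
        kept = classified[classified["kept"]]
        assert set(kept["outcome"]) <= {"hit", "choice_error", "motor_error"}
        assert kept["outcome"].notna().all()
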