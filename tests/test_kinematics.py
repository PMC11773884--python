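"""Kinematic readouts against closed forms and brute-force oracles."""

import numpy as np
import pytest

from finpose.kinematics import (
    Bout,
    KinematicConfig,
    TrajectorySeries,
    angle_series,
    bend_summary,
    compute_speed,
    detect_bends,
    detect_bouts,
    period_summaries,
    response_summary,
    rostral_caudal_angle,
    smooth_series,
    stimulus_summary,
    trajectory_table,
)


def make_traj(positions, framerate=100.0, mm_per_px=0.1, **kw):
    pos = np.asarray(positions, dtype=float)
    return TrajectorySeries(keypoints=pos[:, None, :], framerate=framerate, mm_per_px=mm_per_px, **kw)


# ---------------------------------------------------------------- speed


class TestSpeed:
    def test_stationary_fish_all_zero(self):
        traj = make_traj([[5, 5]] * 10)
        np.testing.assert_array_equal(compute_speed(traj), np.zeros(10))

    def test_constant_step_arithmetic(self):
        # 0.2 px/frame at 100 Hz and 0.1 mm/px -> 2.0 mm/s
        pos = np.stack([np.arange(10) * 0.2, np.zeros(10)], axis=1)
        traj = make_traj(pos)
        speed = compute_speed(traj)
        assert speed[0] == 0.0
        np.testing.assert_allclose(speed[1:], 2.0)

    def test_reference_keypoint_selects_column(self):
        kp = np.zeros((5, 2, 2))
        kp[:, 1, 0] = np.arange(5)  # caudal keypoint moves, rostral still
        traj = TrajectorySeries(keypoints=kp, framerate=10, mm_per_px=1.0)
        assert compute_speed(traj).max() == 0.0
        cfg = KinematicConfig(reference_keypoint=1)
        assert compute_speed(traj, cfg).max() == pytest.approx(10.0)


# ---------------------------------------------------------------- smoothing


class TestSmooth:
    def test_constant_series_unchanged(self):
        x = np.full(300, 2.5)
        np.testing.assert_array_equal(smooth_series(x, 1.0, 100.0), x)

    def test_unit_impulse_plateau(self):
        x = np.zeros(401)
        x[200] = 1.0
        sm = smooth_series(x, 1.0, 100.0)
        # interior plateau of a 1 s window at 100 Hz: 101 frames of 1/101
        assert sm[200] == pytest.approx(1 / 101)
        assert sm[150] == pytest.approx(1 / 101)
        assert sm[149] == 0.0

    def test_mean_preserved_for_interior_series(self):
        rng = np.random.default_rng(0)
        x = np.zeros(1000)
        x[300:700] = rng.uniform(0, 5, 400)
        sm = smooth_series(x, 1.0, 100.0)
        assert abs(sm.mean() - x.mean()) < 1e-9


# ---------------------------------------------------------------- angle


def points_on_arc(total_deg, n=7, radius=10.0):
    """n points equally spaced along a circular arc with tangent turn total_deg."""
    angles = np.radians(np.linspace(0, total_deg, n))
    return np.stack([radius * np.cos(angles), radius * np.sin(angles)], axis=1)


class TestRostralCaudalAngle:
    def test_collinear_keypoints_zero(self):
        kp = np.stack([np.arange(7, dtype=float), np.arange(7, dtype=float) * 2], axis=1)
        assert rostral_caudal_angle(kp) == pytest.approx(0.0, abs=1e-12)

    def test_seven_points_on_a_semicircle_is_150_degrees(self):
        kp = points_on_arc(180.0, n=7)
        assert abs(rostral_caudal_angle(kp)) == pytest.approx(150.0, abs=1e-9)

    def test_mirror_image_negates(self):
        kp = points_on_arc(120.0, n=5)
        mirrored = kp * np.array([1.0, -1.0])
        assert rostral_caudal_angle(mirrored) == pytest.approx(
            -rostral_caudal_angle(kp), abs=1e-9
        )

    def test_rotation_and_translation_invariance(self):
        rng = np.random.default_rng(3)
        kp = points_on_arc(95.0, n=7) + rng.normal(0, 0.3, (7, 2))
        base = rostral_caudal_angle(kp)
        for _ in range(25):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            moved = kp @ rot.T + rng.uniform(-50, 50, 2)
            assert rostral_caudal_angle(moved) == pytest.approx(base, abs=1e-8)

    def test_coincident_keypoints_rejected(self):
        kp = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(ValueError):
            rostral_caudal_angle(kp)


# ---------------------------------------------------------------- bends


def brute_force_bends(angles, framerate, threshold):
    """Independent enumeration: one peak per maximal same-sign run."""
    events = []
    i, n = 0, len(angles)
    while i < n:
        s = np.sign(angles[i])
        if s == 0:
            i += 1
            continue
        j = i
        while j < n and np.sign(angles[j]) == s:
            j += 1
        best = i
        for t in range(i, j):
            if abs(angles[t]) > abs(angles[best]):
                best = t
        events.append((best / framerate, angles[best], abs(angles[best]) >= threshold))
        i = j
    return events


class TestBends:
    def test_high_amplitude_classification_at_110(self):
        # peaks 120, -95, 115 -> two high-amplitude bends
        angles = np.concatenate(
            [
                np.array([0, 60, 120, 60, 0]),
                np.array([-40, -95, -40]),
                np.array([50, 115, 50, 0]),
            ]
        ).astype(float)
        events = detect_bends(angles, framerate=1000.0)
        peaks = [e.peak_angle for e in events]
        assert peaks == [120.0, -95.0, 115.0]
        assert sum(e.is_high_amplitude for e in events) == 2

    def test_triangular_pulse_first_bend_peak_and_time(self):
        framerate = 1000.0
        angles = np.zeros(50)
        # rise to 130 deg at frame 15 (t = 0.015 s), fall back to zero
        angles[6:27] = np.concatenate([np.linspace(0, 130, 11)[1:], np.linspace(130, 0, 12)[1:]])
        events = detect_bends(angles, framerate)
        summary = bend_summary(events, angles, framerate)
        assert summary["first_bend_angle"] == pytest.approx(130.0)
        assert summary["first_bend_time"] == pytest.approx(0.015)
        assert summary["max_angle"] == pytest.approx(130.0)

    def test_all_below_threshold_means_no_high_amplitude(self):
        angles = 100.0 * np.sin(np.linspace(0, 6 * np.pi, 200))
        events = detect_bends(angles, 1000.0)
        assert events and not any(e.is_high_amplitude for e in events)
        assert bend_summary(events, angles, 1000.0)["any_high_amplitude"] is False

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(99)
        cfg = KinematicConfig()
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            angles = rng.normal(0, 80, n).round(0)  # rounding creates zeros/ties
            events = detect_bends(angles, 100.0, cfg)
            oracle = brute_force_bends(angles, 100.0, cfg.bend_threshold)
            assert [(e.peak_time, e.peak_angle, e.is_high_amplitude) for e in events] == oracle


# ---------------------------------------------------------------- bouts


def brute_force_bouts(speed, framerate, threshold):
    bouts = []
    i, n = 0, len(speed)
    while i < n:
        if speed[i] > threshold:
            j = i
            while j < n and speed[j] > threshold:
                j += 1
            bouts.append(
                (i / framerate, (j - 1) / framerate, (j - i) / framerate, max(speed[i:j]))
            )
            i = j
        else:
            i += 1
    return bouts


class TestBouts:
    def test_worked_example(self):
        speed = np.array([0, 0, 5, 6, 5, 0, 0, 3, 0], dtype=float)
        bouts = detect_bouts(speed, 100.0)
        assert len(bouts) == 2
        assert bouts[0].duration == pytest.approx(0.03)
        assert bouts[1].duration == pytest.approx(0.01)
        assert bouts[0].peak_speed == 6.0
        assert bouts[1].peak_speed == 3.0

    def test_all_below_threshold(self):
        assert detect_bouts(np.full(50, 1.9), 100.0) == []

    def test_all_above_threshold_single_bout(self):
        bouts = detect_bouts(np.full(50, 9.0), 100.0)
        assert len(bouts) == 1
        assert bouts[0].duration == pytest.approx(0.5)

    def test_threshold_is_strict(self):
        assert detect_bouts(np.full(10, 2.0), 100.0) == []

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(7)
        cfg = KinematicConfig()
        for _ in range(1000):
            n = int(rng.integers(1, 50))
            speed = rng.choice([0.0, 1.0, 2.0, 3.0, 8.0], size=n)
            got = detect_bouts(speed, 100.0, cfg)
            oracle = brute_force_bouts(speed, 100.0, cfg.bout_threshold)
            assert [
                (b.start_time, b.end_time, b.duration, b.peak_speed) for b in got
            ] == oracle

    def test_bout_count_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        speed = np.abs(rng.normal(0, 4, 500))
        counts = [
            len(detect_bouts(speed, 100.0, KinematicConfig(bout_threshold=t)))
            for t in [1.0, 2.0, 4.0, 8.0]
        ]
        # counts can rise then fall, but bout *frames* shrink; the documented
        # invariant is on total time above threshold:
        frames_above = [(speed > t).sum() for t in [1.0, 2.0, 4.0, 8.0]]
        assert frames_above == sorted(frames_above, reverse=True)
        # and no bouts exist once the threshold exceeds the maximum speed
        assert len(detect_bouts(speed, 100.0, KinematicConfig(bout_threshold=speed.max() + 1))) == 0


# ---------------------------------------------------------------- summaries


class TestStimulusSummary:
    def test_window_is_500_frames_at_100hz(self):
        rng = np.random.default_rng(0)
        pos = np.cumsum(rng.normal(0, 0.2, (1000, 2)), axis=0) + 500
        traj = make_traj(pos, framerate=100.0)
        out = stimulus_summary(traj, mark=2.0)
        speed = compute_speed(traj)
        times = traj.times
        window = speed[(times >= 2.0) & (times < 7.0)]
        assert window.size == 500
        assert out["max_speed"] == pytest.approx(window.max())

    def test_no_bouts_reports_missing_means(self):
        traj = make_traj([[5, 5]] * 200, framerate=100.0)
        out = stimulus_summary(traj, mark=0.5)
        assert out["bout_count"] == 0
        assert np.isnan(out["mean_bout_duration"])
        assert np.isnan(out["mean_bout_peak_speed"])

    def test_truncated_window_warns(self):
        traj = make_traj([[5, 5]] * 100, framerate=100.0)
        with pytest.warns(UserWarning, match="truncat"):
            stimulus_summary(traj, mark=0.9)

    def test_mark_outside_recording_rejected(self):
        traj = make_traj([[5, 5]] * 100, framerate=100.0)
        with pytest.raises(ValueError):
            stimulus_summary(traj, mark=5.0)

    def test_period_summaries_delimited_by_marks(self):
        pos = np.zeros((400, 2))
        pos[100:110] = np.cumsum(np.full((10, 2), 2.0), axis=0)  # one burst
        traj = make_traj(pos + 50, framerate=100.0, stimulus_marks={"light_on": 1.0, "dark_on": 2.0})
        table = period_summaries(traj)
        assert list(table["period"]) == ["start", "light_on", "dark_on"]
        assert table.loc[1, "bout_count"] >= 1
        assert table.loc[2, "bout_count"] == 0


class TestResponseSummary:
    def test_duration_and_distance_arithmetic(self):
        # 250 frames at 1000 Hz; straight travel of 40 px at 0.05 mm/px
        pos = np.stack([np.linspace(0, 40, 250), np.zeros(250)], axis=1)
        traj = make_traj(pos, framerate=1000.0, mm_per_px=0.05)
        out = response_summary(traj)
        assert out["duration"] == pytest.approx(0.25)
        assert out["distance"] == pytest.approx(2.0)
        assert out["progress"][-1] == pytest.approx(1.0)

    def test_trajectory_table_schema(self):
        kp = np.random.default_rng(0).uniform(10, 50, (20, 3, 2))
        traj = TrajectorySeries(keypoints=kp, framerate=100.0, mm_per_px=0.1)
        table = trajectory_table(traj)
        for col in ("frame", "time_s", "x_0", "y_2", "speed_mm_s",
                    "rostral_caudal_angle_deg", "segment_angle_0_deg"):
            assert col in table.columns
        assert len(table) == 20


def test_mm_per_px_must_be_supplied_positive():
    with pytest.raises(ValueError):
        TrajectorySeries(keypoints=np.zeros((5, 1, 2)), framerate=100.0, mm_per_px=0.0)
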