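"""Motion-window detection and the displacement/velocity parameters."""

import numpy as np
import pytest

from hyokin import (
    ExtractionConfig,
    HyoidTrajectory,
    MotionWindow,
    NoMotionError,
    ValidationError,
    compute_displacements,
    compute_velocities,
    detect_motion_window,
    extract_kinematics,
    smooth_trajectory,
)

from conftest import make_recording

FPS = 30.0


def traj_from_xy(x, y, fps=FPS) -> HyoidTrajectory:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return HyoidTrajectory(x=x, y=y, t=np.arange(x.size) / fps, fps=fps)


class TestSmoothing:
    def test_window_one_is_identity(self, rng):
        traj = traj_from_xy(rng.normal(size=40), rng.normal(size=40))
        out = smooth_trajectory(traj, 1)
        assert np.array_equal(out.x, traj.x) and np.array_equal(out.y, traj.y)

    def test_constant_unchanged(self):
        traj = traj_from_xy(np.full(30, 2.5), np.full(30, -1.0))
        out = smooth_trajectory(traj, 7)
        assert np.allclose(out.x, 2.5) and np.allclose(out.y, -1.0)

    def test_linear_ramp_interior_unchanged(self):
        # the centered moving average of a line equals the line
        x = np.arange(30) * 0.3
        out = smooth_trajectory(traj_from_xy(x, -x), 5)
        assert np.allclose(out.x, x)  # shrunken symmetric edges stay exact too
        assert np.allclose(out.y, -x)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError):
            smooth_trajectory(traj_from_xy([0, 1], [0, 0]), 4)


class TestMotionWindow:
    def test_stationary_raises(self):
        with pytest.raises(NoMotionError):
            detect_motion_window(traj_from_xy(np.zeros(40), np.zeros(40)))

    def test_rest_move_rest(self):
        # 10 frames rest, 15 frames at 15 mm/s (0.5 mm/frame), rest
        x = np.concatenate([np.zeros(10), 0.5 * np.arange(1, 16), np.full(15, 7.5)])
        window = detect_motion_window(traj_from_xy(x, np.zeros_like(x)))
        assert abs(window.onset - 10) <= 1
        assert abs(window.offset - 24) <= 1

    def test_short_hold_bridged(self):
        # two suprathreshold runs separated by a 0.3 s hold (< 0.5 s tolerance)
        move = 0.5 * np.arange(1, 11)
        x = np.concatenate([
            np.zeros(10), move, np.full(9, move[-1]),
            move[-1] + 0.5 * np.arange(1, 11), np.full(10, 2 * move[-1]),
        ])
        window = detect_motion_window(traj_from_xy(x, np.zeros_like(x)))
        assert window.onset <= 10
        assert window.offset >= 38  # spans both runs

    def test_long_hold_splits(self):
        move = 0.5 * np.arange(1, 11)
        x = np.concatenate([
            np.zeros(10), move, np.full(20, move[-1]),  # 0.67 s hold
            move[-1] + 0.5 * np.arange(1, 11), np.full(10, 2 * move[-1]),
        ])
        window = detect_motion_window(traj_from_xy(x, np.zeros_like(x)))
        assert window.offset <= 21  # second run excluded

    def test_isolated_spike_not_merged(self):
        move = 0.5 * np.arange(1, 11)
        x = np.concatenate([np.zeros(10), move, np.full(10, move[-1])])
        x[25] += 0.4  # one-frame jitter spike after the true offset
        window = detect_motion_window(traj_from_xy(x, np.zeros_like(x)))
        assert window.offset <= 21


class TestDisplacements:
    def test_pythagorean_three_four_five(self):
        x = np.concatenate([np.zeros(5), np.linspace(0, 3, 10), np.full(5, 3.0)])
        y = np.concatenate([np.zeros(5), np.linspace(0, 4, 10), np.full(5, 4.0)])
        window = MotionWindow(onset=4, offset=19)
        dx, dy, dxy = compute_displacements(traj_from_xy(x, y), window)
        assert (dx, dy, dxy) == pytest.approx((3.0, 4.0, 5.0))

    def test_identical_points_zero(self):
        traj = traj_from_xy(np.full(20, 1.7), np.full(20, -2.2))
        assert compute_displacements(traj, MotionWindow(0, 19)) == (0.0, 0.0, 0.0)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            x = np.cumsum(rng.normal(size=50))
            y = np.cumsum(rng.normal(size=50))
            traj = traj_from_xy(x, y)
            onset = int(rng.integers(0, 20))
            offset = int(rng.integers(onset + 1, 50))
            dx, dy, dxy = compute_displacements(traj, MotionWindow(onset, offset))
            # brute-force frame-by-frame scan
            b_dx = b_dy = b_dxy = -np.inf
            for i in range(onset, offset + 1):
                b_dx = max(b_dx, x[i] - x[onset])
                b_dy = max(b_dy, y[i] - y[onset])
                b_dxy = max(
                    b_dxy, np.hypot(x[i] - x[onset], y[i] - y[onset])
                )
            assert (dx, dy, dxy) == pytest.approx((b_dx, b_dy, b_dxy), abs=1e-12)

    def test_window_monotonicity(self, rng):
        x = np.cumsum(rng.normal(size=60))
        y = np.cumsum(rng.normal(size=60))
        traj = traj_from_xy(x, y)
        prev = (-np.inf,) * 3
        for offset in range(6, 60, 5):
            d = compute_displacements(traj, MotionWindow(5, offset))
            assert all(a >= b - 1e-12 for a, b in zip(d, prev))
            prev = d

    def test_c4_origin_reference(self):
        x = np.linspace(2.0, 5.0, 20)
        y = np.zeros(20)
        d_onset = compute_displacements(traj_from_xy(x, y), MotionWindow(0, 19))
        d_c4 = compute_displacements(
            traj_from_xy(x, y), MotionWindow(0, 19), reference="c4_origin"
        )
        assert d_onset[0] == pytest.approx(3.0)
        assert d_c4[0] == pytest.approx(5.0)


class TestVelocities:
    def test_velocity_duration_identity(self):
        vx, vy, vxy, duration = compute_velocities(
            (3.0, 4.0, 5.0), MotionWindow(10, 40), fps=30.0
        )
        assert duration == pytest.approx(1.0)
        assert (vx, vy, vxy) == pytest.approx((3.0, 4.0, 5.0))
        assert vx * duration == pytest.approx(3.0)

    def test_fps_scaling(self):
        slow = compute_velocities((5.0, 5.0, 5.0), MotionWindow(0, 30), fps=30.0)
        fast = compute_velocities((5.0, 5.0, 5.0), MotionWindow(0, 30), fps=60.0)
        assert fast[3] == pytest.approx(slow[3] / 2)
        assert fast[2] == pytest.approx(slow[2] * 2)


class TestExtraction:
    @staticmethod
    def moving_recording():
        # hyoid moves 10 px anterior (left) and 8 px superior (up) at 0.5 mm/px
        def path(i):
            if i < 15:
                return (90.0, 105.0)
            if i < 30:
                s = (i - 15) / 15
                return (90.0 - 10 * s, 105.0 - 8 * s)
            return (80.0, 97.0)

        return make_recording(n_frames=45, hyoid_path=path)

    def test_manual_window_override(self, raw_config):
        rec = self.moving_recording()
        cfg = ExtractionConfig(
            smoothing_window=1, manual_windows={"test": (15, 30)}
        )
        summary = extract_kinematics(rec, cfg)
        assert summary.window == MotionWindow(15, 30)
        assert summary.dx == pytest.approx(5.0)  # 10 px * 0.5 mm/px
        assert summary.dy == pytest.approx(4.0)
        assert summary.duration_s == pytest.approx(0.5)
        assert summary.vxy == pytest.approx(summary.dxy / 0.5)

    def test_detected_window_close_to_truth(self, raw_config):
        summary = extract_kinematics(self.moving_recording(), raw_config)
        assert summary.dx == pytest.approx(5.0, abs=0.4)
        assert summary.dy == pytest.approx(4.0, abs=0.4)

    def test_stationary_recording_flagged(self, raw_config):
        with pytest.raises(NoMotionError, match="test"):
            extract_kinematics(make_recording(n_frames=40), raw_config)
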