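"""Hyoid motion window detection and the six kinematic parameters.

For each swallow the package reports, in the field's usual notation:

====  =======================================================  =======
Dx    maximal anterior hyoid displacement                      mm
Dy    maximal superior hyoid displacement                      mm
Dxy   maximal hyoid displacement (Euclidean, Pythagorean)      mm
Vx    average velocity of anterior displacement, Dx/duration   mm/s
Vy    average velocity of superior displacement, Dy/duration   mm/s
Vxy   average velocity of maximal displacement, Dxy/duration   mm/s
====  =======================================================  =======

Displacements are measured relative to the hyoid position at motion onset
(the standard hyoid-excursion convention; a ``reference="c4_origin"`` switch
preserves the literal reading of measuring from the C4 origin).  The motion
window runs from the recognizable initiation of hyoid motion to its
termination after the swallow, operationalized as the first sustained run of
frame-to-frame speeds above a threshold through the last suprathreshold run
reachable across sub-threshold holds shorter than a gap tolerance (the peak
hold stays inside the window).  Velocities are the corresponding displacement
divided by the window duration, so V * duration == D exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .anatomy import HyoidTrajectory, hyoid_trajectory
from .errors import NoMotionError, ValidationError
from .landmarks import SwallowRecording

PARAMETERS = ("Dx", "Dy", "Dxy", "Vx", "Vy", "Vxy")


@dataclass(frozen=True)
class MotionWindow:
    """Onset/offset point indices into a trajectory (onset < offset)."""

    onset: int
    offset: int

    def __post_init__(self) -> None:
        if not (0 <= self.onset < self.offset):
            raise ValidationError(
                f"motion window needs 0 <= onset < offset, got "
                f"({self.onset}, {self.offset})"
            )


@dataclass(frozen=True)
class KinematicSummary:
    dx: float
    dy: float
    dxy: float
    duration_s: float
    vx: float
    vy: float
    vxy: float
    window: MotionWindow
    recording_id: str | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "Dx": self.dx,
            "Dy": self.dy,
            "Dxy": self.dxy,
            "duration": self.duration_s,
            "Vx": self.vx,
            "Vy": self.vy,
            "Vxy": self.vxy,
            "onset": self.window.onset,
            "offset": self.window.offset,
        }


@dataclass(frozen=True)
class ExtractionConfig:
    """Tunable knobs of the extraction pipeline.

    smoothing_window
        odd moving-average width in frames (1 disables smoothing); the
        default 5 tames the extreme-value bias of the max under annotation
        jitter.
    speed_threshold_mm_s, min_run_frames, gap_tolerance_s
        motion-window detector settings (see :func:`detect_motion_window`).
    reference
        "onset" (default) or "c4_origin" displacement reference.
    manual_windows
        recording_id -> (onset, offset) overrides for human-judged windows.
    """

    smoothing_window: int = 5
    speed_threshold_mm_s: float = 5.0
    min_run_frames: int = 3
    gap_tolerance_s: float = 0.5
    reference: str = "onset"
    manual_windows: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValidationError(
                f"smoothing_window must be odd and >= 1, got {self.smoothing_window}"
            )
        if self.speed_threshold_mm_s <= 0:
            raise ValidationError("speed_threshold_mm_s must be positive")
        if self.min_run_frames < 1:
            raise ValidationError("min_run_frames must be >= 1")
        if self.gap_tolerance_s < 0:
            raise ValidationError("gap_tolerance_s must be >= 0")
        if self.reference not in ("onset", "c4_origin"):
            raise ValidationError(
                f"reference must be 'onset' or 'c4_origin', got {self.reference!r}"
            )

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "ExtractionConfig":
        manual = {
            str(k): (int(v[0]), int(v[1]))
            for k, v in dict(mapping.get("manual_windows", {})).items()
        }
        kwargs = {k: mapping[k] for k in (
            "smoothing_window", "speed_threshold_mm_s", "min_run_frames",
            "gap_tolerance_s", "reference") if k in mapping}
        return cls(manual_windows=manual, **kwargs)


def smooth_trajectory(traj: HyoidTrajectory, window_frames: int) -> HyoidTrajectory:
    """Centered moving average per coordinate; edges use shrunken symmetric
    windows so the filter stays zero-phase.  ``window_frames=1`` is the
    identity."""
    if window_frames < 1 or window_frames % 2 == 0:
        raise ValidationError(
            f"window_frames must be odd and >= 1, got {window_frames}"
        )
    if window_frames == 1:
        return traj
    half = window_frames // 2
    n = traj.n
    i = np.arange(n)
    h = np.minimum(np.minimum(i, n - 1 - i), half)
    lo, hi = i - h, i + h

    def _ma(v: np.ndarray) -> np.ndarray:
        cs = np.concatenate(([0.0], np.cumsum(v)))
        return (cs[hi + 1] - cs[lo]) / (2 * h + 1)

    return replace(traj, x=_ma(traj.x), y=_ma(traj.y))


def _speed(traj: HyoidTrajectory) -> np.ndarray:
    """Frame-to-frame speeds (mm/s); entry i covers the segment i -> i+1."""
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    dt = np.diff(traj.t)
    return np.hypot(dx, dy) / dt


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, end) index pairs of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(s), int(e - 1)) for s, e in zip(edges[::2], edges[1::2])]


def detect_motion_window(
    traj: HyoidTrajectory,
    speed_threshold_mm_s: float = 5.0,
    min_run_frames: int = 3,
    gap_tolerance_s: float = 0.5,
) -> MotionWindow:
    """Locate the swallow's motion window on a (smoothed) trajectory.

    Onset is the first point starting a run of at least ``min_run_frames``
    consecutive suprathreshold frame-to-frame speeds.  Later qualifying runs
    (same minimum length, so isolated jitter spikes cannot stretch the
    window) are chained into it while the sub-threshold hold separating them
    lasts at most ``gap_tolerance_s``; the offset is the last point of the
    final chained run.  A trajectory with no qualifying run raises
    :class:`~hyokin.errors.NoMotionError` so the recording is flagged rather
    than silently zeroed.
    """
    if traj.n < min_run_frames + 1:
        raise NoMotionError(
            f"trajectory has {traj.n} points, need at least {min_run_frames + 1}"
        )
    speeds = _speed(traj)
    mask = speeds > speed_threshold_mm_s
    runs = [r for r in _runs(mask) if r[1] - r[0] + 1 >= min_run_frames]
    if not runs:
        raise NoMotionError(
            f"no run of {min_run_frames}+ frames above "
            f"{speed_threshold_mm_s} mm/s"
        )
    onset, end = runs[0]
    for start, stop in runs:
        if start <= end:
            continue
        # time from the last suprathreshold instant to the next one
        gap = traj.t[start] - traj.t[end + 1]
        if gap <= gap_tolerance_s:
            end = stop
        else:
            break
    return MotionWindow(onset=onset, offset=end + 1)


def compute_displacements(
    traj: HyoidTrajectory, window: MotionWindow, reference: str = "onset"
) -> tuple[float, float, float]:
    """(Dx, Dy, Dxy) over the window.

    Dx and Dy are signed maxima of the anterior and superior excursion from
    the reference (posterior/inferior motion does not contribute); Dxy is the
    maximal Euclidean displacement from the reference.
    """
    if window.offset >= traj.n:
        raise ValidationError(
            f"window offset {window.offset} outside trajectory of {traj.n} points"
        )
    xs = traj.x[window.onset : window.offset + 1]
    ys = traj.y[window.onset : window.offset + 1]
    if reference == "onset":
        rx, ry = xs[0], ys[0]
    elif reference == "c4_origin":
        rx, ry = 0.0, 0.0
    else:
        raise ValidationError(f"unknown displacement reference {reference!r}")
    dx = xs - rx
    dy = ys - ry
    return float(dx.max()), float(dy.max()), float(np.hypot(dx, dy).max())


def compute_velocities(
    displacements: tuple[float, float, float], window: MotionWindow, fps: float
) -> tuple[float, float, float, float]:
    """(Vx, Vy, Vxy, duration); each V is its D over the window duration."""
    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    duration = (window.offset - window.onset) / fps
    if duration <= 0:
        raise ValidationError("motion window has zero duration")
    d_x, d_y, d_xy = displacements
    return d_x / duration, d_y / duration, d_xy / duration, duration


def extract_kinematics(
    recording: SwallowRecording, config: ExtractionConfig | None = None
) -> KinematicSummary:
    """End-to-end extraction for one validated recording.

    Smooths the anatomical hyoid trajectory, finds the motion window
    (honouring a manual override for this recording_id if configured), and
    computes displacements and average velocities.
    """
    cfg = config or ExtractionConfig()
    rid = recording.meta.recording_id
    traj = hyoid_trajectory(recording)
    smoothed = smooth_trajectory(traj, cfg.smoothing_window)
    if rid in cfg.manual_windows:
        onset, offset = cfg.manual_windows[rid]
        window = MotionWindow(onset=onset, offset=offset)
    else:
        try:
            window = detect_motion_window(
                smoothed,
                speed_threshold_mm_s=cfg.speed_threshold_mm_s,
                min_run_frames=cfg.min_run_frames,
                gap_tolerance_s=cfg.gap_tolerance_s,
            )
        except NoMotionError as exc:
            raise NoMotionError(f"recording {rid!r}: {exc}") from None
    d = compute_displacements(smoothed, window, reference=cfg.reference)
    vx, vy, vxy, duration = compute_velocities(d, window, recording.meta.fps)
    return KinematicSummary(
        dx=d[0], dy=d[1], dxy=d[2], duration_s=duration,
        vx=vx, vy=vy, vxy=vxy, window=window, recording_id=rid,
    )
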