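"""Vertebra-anchored anatomical coordinate frame.

Hyoid positions digitised in image pixels are contaminated by rigid head
motion (the patient translating/rotating within the fluoroscopy field) and by
the unknown image orientation.  Both are removed by re-expressing each frame
in a coordinate system carried by the cervical spine itself:

* origin: anterior-inferior corner of the C4 vertebral body;
* superior axis (+y): the direction of the line through the C5 and C3
  corners, signed so it points from C5 toward C3 (C3 sits superior to C5);
* anterior axis (+x): the perpendicular direction, signed so the mandible
  (always anterior to the spine in lateral view) has positive x.

The sign conventions are fixed by anatomy rather than image handedness, so
left- and right-facing projections need no configuration.  Axes are rebuilt
independently on every frame, which removes head motion frame by frame;
distances are converted to millimetres with the recording's calibration
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateAxisError, MissingLandmarkError, ValidationError
from .landmarks import FrameLandmarks, PixelPoint, SwallowRecording

_AXIS_EPS = 1e-12


@dataclass(frozen=True)
class AnatomicalAxes:
    """Per-frame origin and orthonormal axis directions, in pixel space."""

    origin: PixelPoint
    x_hat: tuple[float, float]
    y_hat: tuple[float, float]


@dataclass(frozen=True)
class AnatomicalPoint:
    """A point in the anatomical frame: anterior x, superior y (mm), time (s)."""

    x: float
    y: float
    t: float


def build_axes(frame: FrameLandmarks) -> AnatomicalAxes:
    """Construct the anatomical axes of one frame.

    Requires c3, c4, c5 and mandible.  Raises
    :class:`~hyokin.errors.DegenerateAxisError` when C3 and C5 coincide or
    the mandible lies on the spinal axis (anterior side undecidable).
    """
    for name in ("c3", "c4", "c5", "mandible"):
        if frame.get(name) is None:
            raise MissingLandmarkError(
                f"frame {frame.frame_index}: landmark {name!r} required for axes"
            )
    c3, c4, c5, mandible = frame.c3, frame.c4, frame.c5, frame.mandible
    vy = (c3.x - c5.x, c3.y - c5.y)
    norm = math.hypot(*vy)
    if norm < _AXIS_EPS:
        raise DegenerateAxisError(
            f"frame {frame.frame_index}: C3 and C5 coincide, no spinal axis"
        )
    y_hat = (vy[0] / norm, vy[1] / norm)
    perp = (y_hat[1], -y_hat[0])
    d = (mandible.x - c4.x) * perp[0] + (mandible.y - c4.y) * perp[1]
    if abs(d) < _AXIS_EPS:
        raise DegenerateAxisError(
            f"frame {frame.frame_index}: mandible lies on the spinal axis, "
            "anterior direction undecidable"
        )
    x_hat = perp if d > 0 else (-perp[0], -perp[1])
    return AnatomicalAxes(origin=c4, x_hat=x_hat, y_hat=y_hat)


def to_anatomical(
    p: PixelPoint, axes: AnatomicalAxes, mm_per_pixel: float, t: float = 0.0
) -> AnatomicalPoint:
    """Project a pixel point onto the anatomical axes and scale to mm."""
    if not (mm_per_pixel > 0 and math.isfinite(mm_per_pixel)):
        raise ValidationError(f"mm_per_pixel must be positive, got {mm_per_pixel}")
    if not math.isfinite(t):
        raise ValidationError(f"time must be finite, got {t}")
    dx = p.x - axes.origin.x
    dy = p.y - axes.origin.y
    return AnatomicalPoint(
        x=mm_per_pixel * (dx * axes.x_hat[0] + dy * axes.x_hat[1]),
        y=mm_per_pixel * (dx * axes.y_hat[0] + dy * axes.y_hat[1]),
        t=t,
    )


@dataclass(frozen=True)
class HyoidTrajectory:
    """Hyoid positions in the anatomical frame over time (mm, s)."""

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        t = np.asarray(self.t, dtype=float)
        if not (x.shape == y.shape == t.shape) or x.ndim != 1:
            raise ValidationError("trajectory arrays must be 1-D and equal length")
        if x.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValidationError("trajectory times must be strictly increasing")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(t))):
            raise ValidationError("trajectory contains non-finite values")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "t", t)

    @property
    def n(self) -> int:
        return self.x.size

    def points(self) -> list[AnatomicalPoint]:
        return [AnatomicalPoint(float(xi), float(yi), float(ti))
                for xi, yi, ti in zip(self.x, self.y, self.t)]


def _stack(frames, name: str) -> np.ndarray:
    return np.array([[f.get(name).x, f.get(name).y] for f in frames], dtype=float)


def hyoid_trajectory(recording: SwallowRecording) -> HyoidTrajectory:
    """Hyoid positions of all complete frames, axes rebuilt per frame.

    Times are ``frame_index / fps``.  Vectorised equivalent of calling
    :func:`build_axes` + :func:`to_anatomical` on every complete frame.
    """
    frames = recording.complete_frames()
    if len(frames) < 2:
        raise ValidationError(
            f"recording {recording.meta.recording_id!r}: fewer than 2 complete frames"
        )
    idx = np.array([f.frame_index for f in frames], dtype=float)
    c3 = _stack(frames, "c3")
    c4 = _stack(frames, "c4")
    c5 = _stack(frames, "c5")
    mand = _stack(frames, "mandible")
    hyoid = _stack(frames, "hyoid")

    vy = c3 - c5
    norms = np.hypot(vy[:, 0], vy[:, 1])
    bad = np.flatnonzero(norms < _AXIS_EPS)
    if bad.size:
        raise DegenerateAxisError(
            f"recording {recording.meta.recording_id!r} frame "
            f"{frames[bad[0]].frame_index}: C3 and C5 coincide"
        )
    y_hat = vy / norms[:, None]
    perp = np.stack([y_hat[:, 1], -y_hat[:, 0]], axis=1)
    d = np.einsum("ij,ij->i", mand - c4, perp)
    bad = np.flatnonzero(np.abs(d) < _AXIS_EPS)
    if bad.size:
        raise DegenerateAxisError(
            f"recording {recording.meta.recording_id!r} frame "
            f"{frames[bad[0]].frame_index}: mandible on the spinal axis"
        )
    x_hat = perp * np.sign(d)[:, None]
    rel = hyoid - c4
    scale = recording.meta.mm_per_pixel
    return HyoidTrajectory(
        x=scale * np.einsum("ij,ij->i", rel, x_hat),
        y=scale * np.einsum("ij,ij->i", rel, y_hat),
        t=idx / recording.meta.fps,
        fps=recording.meta.fps,
    )


def derive_scale_from_c2c4(frame: FrameLandmarks, known_distance_mm: float) -> float:
    """Calibration helper: mm-per-pixel from a known C2-C4 corner distance.

    Off by default in the pipeline -- the documented metadata field is the
    primary calibration -- but useful when a recording ships without one.
    """
    if not (known_distance_mm > 0 and math.isfinite(known_distance_mm)):
        raise ValidationError(
            f"known_distance_mm must be positive, got {known_distance_mm}"
        )
    for name in ("c2", "c4"):
        if frame.get(name) is None:
            raise MissingLandmarkError(
                f"frame {frame.frame_index}: landmark {name!r} required"
            )
    dist_px = math.hypot(frame.c2.x - frame.c4.x, frame.c2.y - frame.c4.y)
    if dist_px < _AXIS_EPS:
        raise DegenerateAxisError(
            f"frame {frame.frame_index}: C2 and C4 coincide, cannot calibrate"
        )
    return known_distance_mm / dist_px
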