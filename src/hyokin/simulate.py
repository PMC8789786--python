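"""Synthetic lateral-view swallow recordings with known ground truth.

The clinical videos behind the published group statistics are not deposited,
so this module provides a forward model that emits landmark-level recordings
with the same statistical structure the analysis assumes.  Each group's
calibration parameter is drawn from a three-parameter shifted log-normal
fitted so its mean and first/third quartiles reproduce a printed
(mean, q1, q3) triple; a swallow trajectory is then synthesised whose
pipeline-extractable value of that parameter equals the draw, and the scene
is rendered to pixel landmarks under configurable rigid head motion and
annotation jitter.

Only one parameter per run can be calibrated exactly: the six kinematic
parameters are mutually constrained through the direction angle and the
duration, so each simulation fixes a single ``calibration_target`` and
derives the rest of the trajectory from it.

Trajectory shape: the hyoid travels from rest along a fixed
anterior-superior direction with a minimum-jerk rise, pauses at the peak,
and returns with a minimum-jerk profile.  When the drawn motion duration is
long relative to the achievable amplitude, a plain peak pause would fall
under the motion detector's speed threshold and split the window, so the
pause is filled with small "re-pump" oscillations just below the peak
(partial descents and recoveries, as seen in effortful or piecemeal
swallows) that keep the frame-to-frame speed detectable.  Segment timing is
solved so that the *suprathreshold* span of the trajectory -- what the
default detector actually measures -- equals the drawn duration, and the
peak amplitude is corrected for the small displacement already accrued at
detection onset, so extracted parameters match ground truth up to frame
discretization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .errors import ValidationError
from .landmarks import (
    CONSISTENCIES,
    FrameLandmarks,
    PixelPoint,
    RecordingMeta,
    SwallowRecording,
)

# ---------------------------------------------------------------------------
# Published per-group calibration triples (mean, q1, q3)
#
# Units: displacements mm, velocities mm/s.  These drive the default group
# models and the calibration-recovery checks.

TABLE_STATS: dict[str, dict[str, tuple[float, float, float]]] = {
    "Dx": {
        "normal": (17.03, 12.12, 21.67),
        "aspiration": (11.50, 7.37, 14.80),
        "stasis": (12.98, 8.72, 16.99),
    },
    "Dy": {
        "normal": (20.63, 13.30, 26.96),
        "aspiration": (19.73, 12.22, 24.85),
        "stasis": (18.88, 12.84, 24.13),
    },
    "Dxy": {
        "normal": (29.85, 21.26, 33.09),
        "aspiration": (25.37, 18.31, 28.64),
        "stasis": (23.69, 18.15, 28.33),
    },
    "Vx": {
        "normal": (19.18, 7.78, 25.47),
        "aspiration": (7.88, 2.05, 9.51),
        "stasis": (15.76, 7.80, 20.02),
    },
    "Vy": {
        "normal": (24.49, 11.53, 34.15),
        "aspiration": (16.32, 5.91, 22.67),
        "stasis": (24.86, 13.06, 34.04),
    },
    "Vxy": {
        "normal": (28.27, 14.73, 40.41),
        "aspiration": (16.48, 5.75, 23.30),
        "stasis": (29.54, 16.99, 38.46),
    },
}

#: Default cohort composition (recordings per group).
GROUP_SIZES = {"normal": 230, "aspiration": 87, "stasis": 132}

_DISPLACEMENT_TARGETS = ("Dx", "Dy", "Dxy")
_VELOCITY_TARGETS = ("Vx", "Vy", "Vxy")


# ---------------------------------------------------------------------------
# Calibrated value distributions

@dataclass(frozen=True)
class CalibratedDistribution:
    """A positive right-skewed distribution fitted to (mean, q1, q3).

    Primary family: shifted log-normal ``shift + LogNormal(mu, sigma)``,
    which can hit any triple with mean above the quartile midpoint.  For
    infeasible triples a gamma matched to (mean, q3) is used instead.
    Draws are floored at a small positive value.
    """

    kind: str  # "shifted_lognormal" | "gamma"
    params: tuple[float, ...]

    def mean(self) -> float:
        if self.kind == "shifted_lognormal":
            shift, mu, sigma = self.params
            return shift + math.exp(mu + sigma**2 / 2)
        shape, scale = self.params
        return shape * scale

    def ppf(self, q) -> np.ndarray | float:
        if self.kind == "shifted_lognormal":
            shift, mu, sigma = self.params
            return shift + np.exp(mu + sigma * sps.norm.ppf(q))
        shape, scale = self.params
        return sps.gamma.ppf(q, a=shape, scale=scale)

    def rvs(self, rng: np.random.Generator, size=None, floor: float = 1e-3):
        if self.kind == "shifted_lognormal":
            shift, mu, sigma = self.params
            draws = shift + rng.lognormal(mu, sigma, size)
        else:
            shape, scale = self.params
            draws = rng.gamma(shape, scale, size)
        return np.maximum(draws, floor)


def fit_calibrated_distribution(
    mean: float, q1: float, q3: float
) -> CalibratedDistribution:
    """Fit a shifted log-normal whose mean/25th/75th percentiles match the
    triple (to ~1e-9 relative error); fall back to a gamma matched to
    (mean, q3), with a warning, when no such log-normal exists."""
    if not all(map(math.isfinite, (mean, q1, q3))):
        raise ValidationError("calibration triple must be finite")
    if q1 >= q3:
        raise ValidationError(f"q1 must be < q3, got q1={q1}, q3={q3}")
    z75 = float(sps.norm.ppf(0.75))

    def implied_mean(sigma: float) -> float:
        em = (q3 - q1) / (2.0 * math.sinh(sigma * z75))
        shift = q1 - em * math.exp(-sigma * z75)
        return shift + em * math.exp(sigma**2 / 2.0)

    target_gap = mean - (q1 + q3) / 2.0
    if target_gap <= 0:
        warnings.warn(
            f"triple (mean={mean}, q1={q1}, q3={q3}) has mean at or below the "
            "quartile midpoint; no right-skewed shifted log-normal matches -- "
            "falling back to a gamma matched to (mean, q3)",
            stacklevel=2,
        )
        return _fit_gamma(mean, q3)
    lo, hi = 1e-6, 0.25
    while implied_mean(hi) - mean < 0:
        hi *= 2.0
        if hi > 64:
            warnings.warn(
                f"no shifted log-normal fits (mean={mean}, q1={q1}, q3={q3}); "
                "falling back to a gamma matched to (mean, q3)",
                stacklevel=2,
            )
            return _fit_gamma(mean, q3)
    sigma = optimize.brentq(
        lambda s: implied_mean(s) - mean, lo, hi, xtol=1e-14, rtol=8.9e-16
    )
    em = (q3 - q1) / (2.0 * math.sinh(sigma * z75))
    shift = q1 - em * math.exp(-sigma * z75)
    return CalibratedDistribution(
        kind="shifted_lognormal", params=(shift, math.log(em), sigma)
    )


def _fit_gamma(mean: float, q3: float) -> CalibratedDistribution:
    if mean <= 0:
        raise ValidationError(f"gamma fallback needs a positive mean, got {mean}")

    def resid(log_shape: float) -> float:
        shape = math.exp(log_shape)
        return float(sps.gamma.ppf(0.75, a=shape, scale=mean / shape)) - q3

    grid = np.linspace(-7, 14, 43)
    vals = [resid(g) for g in grid]
    bracket = next(
        ((grid[i], grid[i + 1]) for i in range(len(grid) - 1)
         if vals[i] * vals[i + 1] <= 0),
        None,
    )
    if bracket is None:
        raise ValidationError(
            f"no gamma distribution matches mean={mean}, q3={q3}"
        )
    log_shape = optimize.brentq(resid, *bracket, xtol=1e-13)
    shape = math.exp(log_shape)
    return CalibratedDistribution(kind="gamma", params=(shape, mean / shape))


# ---------------------------------------------------------------------------
# Scene and group models

@dataclass(frozen=True)
class SceneModel:
    """Geometry, calibration and noise of the synthetic lateral view.

    Distances are millimetres in an anatomical scene frame (x anterior,
    y superior, C4 corner at the origin).  The C2-C5 anterior-inferior
    corners are collinear with uniform spacing, a deliberately clean spine so
    the coordinate construction's ground truth is exact.  Head motion is a
    slow rigid sinusoidal translation plus rotation about the C4 rest
    position; per-recording amplitudes are drawn uniformly up to the maxima.
    Jitter is i.i.d. Gaussian annotation noise added per landmark per frame
    in pixel space.
    """

    spine_spacing_mm: float = 15.0
    mandible_offset_mm: tuple[float, float] = (40.0, 20.0)
    hyoid_rest_mm: tuple[float, float] = (30.0, 10.0)
    mm_per_pixel: float = 0.25
    image_origin_px: tuple[float, float] = (256.0, 256.0)
    head_translation_max_mm: float = 2.0
    head_rotation_max_deg: float = 3.0
    head_period_range_s: tuple[float, float] = (2.0, 5.0)
    jitter_sigma_mm: float = 0.125
    rest_padding_s: float = 0.5

    def __post_init__(self) -> None:
        if self.spine_spacing_mm <= 0 or self.mm_per_pixel <= 0:
            raise ValidationError("geometry parameters must be positive")
        if self.jitter_sigma_mm < 0:
            raise ValidationError("jitter_sigma_mm must be >= 0")
        if self.head_translation_max_mm < 0 or self.head_rotation_max_deg < 0:
            raise ValidationError("head-motion amplitudes must be >= 0")
        if self.rest_padding_s < 0.2:
            raise ValidationError("rest_padding_s must be >= 0.2")

    def quiet(self) -> "SceneModel":
        """Copy with head motion and jitter switched off."""
        return replace(
            self,
            head_translation_max_mm=0.0,
            head_rotation_max_deg=0.0,
            jitter_sigma_mm=0.0,
        )

    def rest_points(self) -> dict[str, np.ndarray]:
        s = self.spine_spacing_mm
        return {
            "c2": np.array([0.0, 2 * s]),
            "c3": np.array([0.0, s]),
            "c4": np.array([0.0, 0.0]),
            "c5": np.array([0.0, -s]),
            "mandible": np.asarray(self.mandible_offset_mm, dtype=float),
            "hyoid": np.asarray(self.hyoid_rest_mm, dtype=float),
        }


@dataclass(frozen=True)
class TrueKinematics:
    """One drawn swallow: which parameter is calibrated, its value, the
    motion duration and the direction angle (degrees from anterior axis)."""

    calibration_target: str
    value: float
    duration_s: float
    angle_deg: float

    def __post_init__(self) -> None:
        if self.calibration_target not in _DISPLACEMENT_TARGETS + _VELOCITY_TARGETS:
            raise ValidationError(
                f"unknown calibration target {self.calibration_target!r}"
            )
        if not self.value > 0:
            raise ValidationError("drawn value must be positive")
        if not self.duration_s > 0:
            raise ValidationError("duration must be positive")
        if not 0 < self.angle_deg < 90:
            raise ValidationError("angle_deg must lie in (0, 90)")


@dataclass(frozen=True)
class GroundTruth:
    """The pipeline-extractable parameter values realized by a synthetic
    swallow (after amplitude floors and duration caps)."""

    calibration_target: str
    value: float
    dx: float
    dy: float
    dxy: float
    duration_s: float
    vx: float
    vy: float
    vxy: float
    angle_deg: float

    def as_dict(self) -> dict[str, float]:
        return {
            "calibration_target": self.calibration_target,
            "true_value": self.value,
            "Dx_true": self.dx, "Dy_true": self.dy, "Dxy_true": self.dxy,
            "duration_true": self.duration_s,
            "Vx_true": self.vx, "Vy_true": self.vy, "Vxy_true": self.vxy,
            "angle_deg": self.angle_deg,
        }


@dataclass(frozen=True)
class GroupKinematicsModel:
    """Per-group generative model: calibrated distribution for one target
    parameter, a log-normal motion-duration distribution, and a uniform
    direction-angle distribution."""

    group: str
    calibration_target: str
    distribution: CalibratedDistribution
    duration_median_s: float = 1.0
    duration_sigma: float = 0.3
    angle_range_deg: tuple[float, float] = (40.0, 60.0)

    def __post_init__(self) -> None:
        if self.duration_median_s <= 0 or self.duration_sigma < 0:
            raise ValidationError("duration parameters must be positive")
        lo, hi = self.angle_range_deg
        if not (0 < lo <= hi < 90):
            raise ValidationError("angle range must satisfy 0 < lo <= hi < 90")

    def draw(self, rng: np.random.Generator) -> TrueKinematics:
        value = float(self.distribution.rvs(rng))
        duration = float(
            self.duration_median_s * math.exp(rng.normal(0.0, self.duration_sigma))
        )
        angle = float(rng.uniform(*self.angle_range_deg))
        return TrueKinematics(
            calibration_target=self.calibration_target,
            value=value, duration_s=duration, angle_deg=angle,
        )


def model_from_table(
    group: str, calibration_target: str = "Dx", **overrides
) -> GroupKinematicsModel:
    """Group model whose target distribution is calibrated to the published
    (mean, q1, q3) triple for that group and parameter."""
    try:
        triple = TABLE_STATS[calibration_target][group]
    except KeyError:
        raise ValidationError(
            f"no calibration triple for ({calibration_target!r}, {group!r})"
        ) from None
    dist = fit_calibrated_distribution(*triple)
    defaults = _default_model_settings(group)
    defaults.update(overrides)
    return GroupKinematicsModel(
        group=group, calibration_target=calibration_target,
        distribution=dist, **defaults,
    )


def _default_model_settings(group: str) -> dict:
    """Angle and duration settings that make one Dx-calibrated trajectory
    family consistent with the published Dy and Vxy group means.

    The direction angle is centred where tan(theta) equals the group's
    Dy/Dx mean ratio (so superior excursion barely separates the groups, as
    published), and the duration median makes Dxy/duration match the group's
    Vxy mean.
    """
    dx_mean = TABLE_STATS["Dx"][group][0]
    dy_mean = TABLE_STATS["Dy"][group][0]
    vxy_mean = TABLE_STATS["Vxy"][group][0]
    theta_c = math.degrees(math.atan2(dy_mean, dx_mean))
    dxy_mean = dx_mean / math.cos(math.radians(theta_c))
    return {
        "angle_range_deg": (theta_c - 5.0, theta_c + 5.0),
        "duration_median_s": dxy_mean / vxy_mean,
    }


def default_group_models() -> dict[str, GroupKinematicsModel]:
    """The cohort-level study conditions: three Dx-calibrated group models."""
    return {g: model_from_table(g, "Dx") for g in GROUP_SIZES}


# ---------------------------------------------------------------------------
# Trajectory synthesis

_MIN_AMPLITUDE_MM = 2.0   # smallest excursion the default detector can see
_MAX_DURATION_S = 8.0
_MIN_DURATION_S = 0.5
_PEAK_HOLD_S = 0.2
_PUMP_AMPLITUDE_MM = 1.6
_PUMP_HALF_PERIOD_S = 0.22


def _mj_pos(tau: np.ndarray | float):
    """Minimum-jerk position profile on [0, 1]."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def _crossing_tau(amplitude: float, seg_time: float, threshold: float) -> float:
    """Phase at which a minimum-jerk segment's speed first exceeds the
    threshold; NaN when the whole segment stays below it."""
    ratio = threshold * seg_time / (30.0 * amplitude)
    disc = 1.0 - 4.0 * math.sqrt(ratio)
    if disc < 0:
        return math.nan
    return (1.0 - math.sqrt(disc)) / 2.0


@dataclass(frozen=True)
class _Segment:
    t0: float
    t1: float
    s0: float
    s1: float  # min-jerk interpolation between s0 and s1 (hold when equal)


@dataclass(frozen=True)
class _Profile:
    segments: tuple[_Segment, ...]
    amplitude: float
    total_time: float
    onset_time: float   # first suprathreshold instant
    offset_time: float  # last suprathreshold instant
    onset_position: float

    def eval(self, t: np.ndarray) -> np.ndarray:
        s = np.zeros_like(t, dtype=float)
        for seg in self.segments:
            m = (t >= seg.t0) & (t < seg.t1)
            if not m.any():
                continue
            if seg.s0 == seg.s1:
                s[m] = seg.s0
            else:
                tau = (t[m] - seg.t0) / (seg.t1 - seg.t0)
                s[m] = seg.s0 + (seg.s1 - seg.s0) * _mj_pos(tau)
        s[t >= self.segments[-1].t1] = self.segments[-1].s1
        return s


def _build_profile(
    d_target: float,
    duration_s: float,
    speed_threshold: float = 5.0,
    rest_padding_s: float = 0.5,
) -> _Profile:
    """Scalar excursion profile whose detectable window reproduces
    (d_target, duration_s).

    The amplitude is solved so that the displacement measured from the
    detection-onset position equals ``d_target``, and segment times so that
    the span between the first and last suprathreshold instants equals
    ``duration_s``.
    """
    if d_target < 0.5 * _MIN_AMPLITUDE_MM:
        raise ValidationError(
            f"target displacement {d_target} below the detectable minimum"
        )
    dur = float(duration_s)
    amp = d_target
    t_rise = tau1 = 0.0
    for _ in range(6):
        t_rise = min(0.1875 * amp, 0.44 * amp ** (1.0 / 3.0), (dur - _PEAK_HOLD_S) / 2.0)
        tau1 = _crossing_tau(amp, t_rise, speed_threshold)
        amp = d_target / (1.0 - _mj_pos(tau1))
    t1 = tau1 * t_rise
    t_mid = dur + 2.0 * t1 - 2.0 * t_rise

    segments: list[_Segment] = []
    t = rest_padding_s
    segments.append(_Segment(0.0, t, 0.0, 0.0))
    segments.append(_Segment(t, t + t_rise, 0.0, amp))
    t += t_rise
    if t_mid <= 0.35:
        segments.append(_Segment(t, t + t_mid, amp, amp))
        t += t_mid
    else:
        pump_amp = min(_PUMP_AMPLITUDE_MM, 0.6 * amp)
        n_half = 2 * max(1, math.ceil((t_mid - 0.35) / (2.0 * _PUMP_HALF_PERIOD_S)))
        pump_time = n_half * _PUMP_HALF_PERIOD_S
        if pump_time > t_mid - 0.1:
            tau_p = (t_mid - 0.1) / n_half
            hold = 0.05
        else:
            tau_p = _PUMP_HALF_PERIOD_S
            hold = (t_mid - pump_time) / 2.0
        segments.append(_Segment(t, t + hold, amp, amp))
        t += hold
        level = amp
        for _ in range(n_half):
            nxt = amp - pump_amp if level == amp else amp
            segments.append(_Segment(t, t + tau_p, level, nxt))
            t += tau_p
            level = nxt
        segments.append(_Segment(t, t + hold, amp, amp))
        t += hold
    segments.append(_Segment(t, t + t_rise, amp, 0.0))
    t += t_rise
    segments.append(_Segment(t, t + rest_padding_s, 0.0, 0.0))
    total = t + rest_padding_s
    onset = rest_padding_s + t1
    offset = t - t_rise + (t_rise - t1)
    return _Profile(
        segments=tuple(segments), amplitude=amp, total_time=total,
        onset_time=onset, offset_time=offset,
        onset_position=amp * _mj_pos(tau1),
    )


def _resolve_target(true_kin: TrueKinematics) -> tuple[float, float, GroundTruth]:
    """Map a drawn (target, value, duration, angle) onto a feasible
    (peak displacement, duration) pair and the realized ground truth."""
    theta = math.radians(true_kin.angle_deg)
    comp = {
        "Dx": math.cos(theta), "Vx": math.cos(theta),
        "Dy": math.sin(theta), "Vy": math.sin(theta),
        "Dxy": 1.0, "Vxy": 1.0,
    }[true_kin.calibration_target]
    dur = min(max(true_kin.duration_s, _MIN_DURATION_S), _MAX_DURATION_S)
    value = true_kin.value
    if true_kin.calibration_target in _DISPLACEMENT_TARGETS:
        dxy = value / comp
        if dxy < _MIN_AMPLITUDE_MM:          # amplitude floor: truncate draw
            dxy = _MIN_AMPLITUDE_MM
    else:
        dxy = value * dur / comp
        if dxy < _MIN_AMPLITUDE_MM:
            # keep the drawn velocity by stretching the window instead
            dur = _MIN_AMPLITUDE_MM * comp / value
            if dur > _MAX_DURATION_S:        # velocity floor: truncate draw
                dur = _MAX_DURATION_S
            dxy = _MIN_AMPLITUDE_MM
    gt = GroundTruth(
        calibration_target=true_kin.calibration_target,
        value=dxy * comp if true_kin.calibration_target in _DISPLACEMENT_TARGETS
        else dxy * comp / dur,
        dx=dxy * math.cos(theta), dy=dxy * math.sin(theta), dxy=dxy,
        duration_s=dur,
        vx=dxy * math.cos(theta) / dur, vy=dxy * math.sin(theta) / dur,
        vxy=dxy / dur,
        angle_deg=true_kin.angle_deg,
    )
    return dxy, dur, gt


def _measure_profile(
    profile: _Profile, fps: float, config
) -> tuple[float, float] | None:
    """What the default pipeline would measure on the noise-free profile:
    (displacement from onset, window duration) after sampling on the frame
    grid, smoothing, and motion-window detection."""
    from .anatomy import HyoidTrajectory
    from .kinematics import detect_motion_window, smooth_trajectory

    n = int(round(profile.total_time * fps)) + 1
    t = np.arange(n) / fps
    s = profile.eval(t)
    traj = HyoidTrajectory(x=s, y=np.zeros_like(s), t=t, fps=fps)
    smoothed = smooth_trajectory(traj, config.smoothing_window)
    try:
        window = detect_motion_window(
            smoothed,
            speed_threshold_mm_s=config.speed_threshold_mm_s,
            min_run_frames=config.min_run_frames,
            gap_tolerance_s=config.gap_tolerance_s,
        )
    except Exception:
        return None
    seg = smoothed.x[window.onset : window.offset + 1]
    return float(seg.max() - seg[0]), (window.offset - window.onset) / fps


def _calibrated_profile(
    dxy: float, dur: float, fps: float, rest_padding_s: float, config
) -> _Profile:
    """Build the excursion profile, nudging amplitude and span so that the
    stated detector measures (dxy, dur) on the noise-free trajectory, up to
    frame discretization."""
    d_adj, dur_adj = dxy, dur
    profile = _build_profile(
        d_adj, dur_adj, speed_threshold=config.speed_threshold_mm_s,
        rest_padding_s=rest_padding_s,
    )
    for _ in range(3):
        measured = _measure_profile(profile, fps, config)
        if measured is None:
            break
        d_meas, dur_meas = measured
        d_adj = max(d_adj + (dxy - d_meas), 0.5 * _MIN_AMPLITUDE_MM)
        dur_adj = max(dur_adj + (dur - dur_meas), 0.45)
        profile = _build_profile(
            d_adj, dur_adj, speed_threshold=config.speed_threshold_mm_s,
            rest_padding_s=rest_padding_s,
        )
    return profile


def synthesize_trajectory(
    true_kin: TrueKinematics,
    scene: SceneModel | None = None,
    fps: float = 30.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    meta: RecordingMeta | None = None,
    calibrate_to: "ExtractionConfig | None" = None,
) -> tuple[SwallowRecording, GroundTruth]:
    """Render one synthetic swallow to pixel-space landmark annotations.

    Ground truth is defined operationally: the values the extraction
    pipeline (``calibrate_to``, default settings when None) measures on the
    noise-free trajectory, so the generator's timing and amplitude are
    calibrated against the same smoothed, frame-discretized detector the
    analysis uses.  With the same seed and arguments the output is
    bit-identical.
    """
    from .kinematics import ExtractionConfig

    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    scene = scene or SceneModel()
    config = calibrate_to or ExtractionConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    dxy, dur, gt = _resolve_target(true_kin)
    profile = _calibrated_profile(
        dxy, dur, fps, scene.rest_padding_s, config
    )
    n_frames = int(round(profile.total_time * fps)) + 1
    t = np.arange(n_frames) / fps
    s = profile.eval(t)
    theta = math.radians(true_kin.angle_deg)
    direction = np.array([math.cos(theta), math.sin(theta)])

    rest = scene.rest_points()
    points = {name: np.tile(p, (n_frames, 1)) for name, p in rest.items()}
    points["hyoid"] = rest["hyoid"][None, :] + s[:, None] * direction[None, :]

    if scene.head_translation_max_mm > 0 or scene.head_rotation_max_deg > 0:
        amp_t = rng.uniform(0.0, scene.head_translation_max_mm)
        dir_t = rng.uniform(0.0, 2.0 * math.pi)
        period_t = rng.uniform(*scene.head_period_range_s)
        phase_t = rng.uniform(0.0, 2.0 * math.pi)
        amp_r = math.radians(rng.uniform(0.0, scene.head_rotation_max_deg))
        period_r = rng.uniform(*scene.head_period_range_s)
        phase_r = rng.uniform(0.0, 2.0 * math.pi)
        shift = (
            amp_t
            * np.sin(2.0 * math.pi * t / period_t + phase_t)[:, None]
            * np.array([math.cos(dir_t), math.sin(dir_t)])[None, :]
        )
        alpha = amp_r * np.sin(2.0 * math.pi * t / period_r + phase_r)
        ca, sa = np.cos(alpha), np.sin(alpha)
        for name, q in points.items():
            rx = ca * q[:, 0] - sa * q[:, 1] + shift[:, 0]
            ry = sa * q[:, 0] + ca * q[:, 1] + shift[:, 1]
            points[name] = np.stack([rx, ry], axis=1)

    ox, oy = scene.image_origin_px
    mmpp = scene.mm_per_pixel
    pixels = {}
    for name, q in points.items():
        px = ox + q[:, 0] / mmpp
        py = oy - q[:, 1] / mmpp
        pixels[name] = np.stack([px, py], axis=1)
    if scene.jitter_sigma_mm > 0:
        sigma_px = scene.jitter_sigma_mm / mmpp
        for name in pixels:
            pixels[name] = pixels[name] + rng.normal(0.0, sigma_px, (n_frames, 2))

    if meta is None:
        meta = RecordingMeta(
            recording_id="synthetic", fps=fps, mm_per_pixel=mmpp,
        )
    frames = [
        FrameLandmarks(
            frame_index=i,
            **{
                name: PixelPoint(float(pixels[name][i, 0]), float(pixels[name][i, 1]))
                for name in pixels
            },
        )
        for i in range(n_frames)
    ]
    return SwallowRecording(meta=meta, frames=frames), gt


# ---------------------------------------------------------------------------
# Cohort simulation

_LABEL_CHOICES = {
    "normal": ([1], [0, 1]),
    "aspiration": ([6, 7, 8], [0, 1]),
    "stasis": ([1], [2, 3, 4]),
}


@dataclass(frozen=True)
class CohortResult:
    recordings: tuple[SwallowRecording, ...]
    truth: pd.DataFrame


def simulate_cohort(
    models: Mapping[str, GroupKinematicsModel] | None = None,
    n_per_group: Mapping[str, int] | None = None,
    scene: SceneModel | None = None,
    fps: float = 30.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> CohortResult:
    """Simulate a labelled cohort with per-recording ground truth.

    PAS / residue scores are drawn uniformly within each group's defining
    range, so every recording round-trips to its group through
    :func:`hyokin.grouping.assign_group` and none is doubly affected.
    """
    models = dict(models) if models is not None else default_group_models()
    n_per_group = dict(n_per_group) if n_per_group is not None else {
        g: GROUP_SIZES[g] for g in models
    }
    unknown = set(n_per_group) - set(models)
    if unknown:
        raise ValidationError(f"n_per_group names unknown groups {sorted(unknown)}")
    if any(n < 1 for n in n_per_group.values()):
        raise ValidationError("n_per_group entries must be >= 1")
    scene = scene or SceneModel()
    if rng is None:
        rng = np.random.default_rng(seed)

    recordings: list[SwallowRecording] = []
    rows: list[dict] = []
    for group, model in models.items():
        if group not in _LABEL_CHOICES:
            raise ValidationError(f"unknown group {group!r}")
        pas_pool, residue_pool = _LABEL_CHOICES[group]
        for i in range(n_per_group.get(group, 0)):
            tk = model.draw(rng)
            meta = RecordingMeta(
                recording_id=f"{group}-{i:04d}",
                fps=fps,
                mm_per_pixel=scene.mm_per_pixel,
                pas=int(rng.choice(pas_pool)),
                mbsimp_residue=int(rng.choice(residue_pool)),
                consistency=str(rng.choice(CONSISTENCIES)),
            )
            rec, gt = synthesize_trajectory(
                tk, scene=scene, fps=fps, rng=rng, meta=meta
            )
            recordings.append(rec)
            rows.append({
                "recording_id": meta.recording_id, "group": group,
                "pas": meta.pas, "mbsimp_residue": meta.mbsimp_residue,
                "consistency": meta.consistency, **gt.as_dict(),
            })
    return CohortResult(recordings=tuple(recordings), truth=pd.DataFrame(rows))
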