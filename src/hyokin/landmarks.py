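"""Per-recording landmark annotations: domain types, file I/O and validation.

A recording is a lateral-view fluoroscopy video annotated frame by frame with
six bony points of interest: the anterior-inferior corners of the C2-C5
vertebral bodies, the anterior-inferior corner of the hyoid bone, and the most
prominent anterior-inferior point of the mandible.  Coordinates are stored in
raw pixel units (image convention: x grows rightward, y grows downward);
calibration to millimetres happens downstream so the annotation files stay
lossless.

Two equivalent on-disk schemas are supported:

* long-format CSV -- leading ``# key=value`` metadata lines, then one row per
  (frame, landmark) with columns ``frame_index,landmark,x,y``; a missing
  landmark is encoded as empty ``x`` and ``y`` cells;
* JSON -- ``{"schema": "hyokin-recording", "meta": {...}, "frames": [...]}``
  with ``null`` for missing landmarks.

Both are UTF-8 with '.' as the decimal separator.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

from .errors import ParseError, ValidationError

LANDMARK_NAMES = ("c2", "c3", "c4", "c5", "hyoid", "mandible")
CONSISTENCIES = ("thin", "thick", "paste")

_CSV_MAGIC = "hyokin-recording"
_JSON_SCHEMA = "hyokin-recording"


@dataclass(frozen=True)
class PixelPoint:
    """A 2-D point in image pixel coordinates (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(
                f"pixel coordinates must be finite, got ({self.x}, {self.y})"
            )


@dataclass(frozen=True)
class FrameLandmarks:
    """The six annotated points of one video frame; absent points are None."""

    frame_index: int
    c2: PixelPoint | None = None
    c3: PixelPoint | None = None
    c4: PixelPoint | None = None
    c5: PixelPoint | None = None
    hyoid: PixelPoint | None = None
    mandible: PixelPoint | None = None

    def __post_init__(self) -> None:
        if int(self.frame_index) != self.frame_index or self.frame_index < 0:
            raise ValidationError(
                f"frame_index must be a non-negative integer, got {self.frame_index}"
            )

    def get(self, name: str) -> PixelPoint | None:
        if name not in LANDMARK_NAMES:
            raise ValidationError(f"unknown landmark name {name!r}")
        return getattr(self, name)

    @property
    def is_complete(self) -> bool:
        return all(getattr(self, n) is not None for n in LANDMARK_NAMES)


@dataclass(frozen=True)
class RecordingMeta:
    """Recording-level metadata.

    ``pas`` is the Penetration-Aspiration Scale score (1-8) and
    ``mbsimp_residue`` the MBSImP pharyngeal-residue component (0-4) assigned
    to the swallow by a trained rater; they drive downstream group assignment
    and are passed through otherwise untouched.
    """

    recording_id: str
    fps: float = 30.0
    mm_per_pixel: float = 0.25
    pas: int = 1
    mbsimp_residue: int = 0
    consistency: str = "thin"
    bolus_volume_ml: float = 5.0

    def __post_init__(self) -> None:
        if not self.recording_id:
            raise ValidationError("recording_id must be non-empty")
        if not (self.fps > 0 and math.isfinite(self.fps)):
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if not (self.mm_per_pixel > 0 and math.isfinite(self.mm_per_pixel)):
            raise ValidationError(
                f"mm_per_pixel must be positive, got {self.mm_per_pixel}"
            )
        if int(self.pas) != self.pas or not 1 <= self.pas <= 8:
            raise ValidationError(f"pas must be an integer in [1, 8], got {self.pas}")
        if int(self.mbsimp_residue) != self.mbsimp_residue or not (
            0 <= self.mbsimp_residue <= 4
        ):
            raise ValidationError(
                f"mbsimp_residue must be an integer in [0, 4], got {self.mbsimp_residue}"
            )
        if self.consistency not in CONSISTENCIES:
            raise ValidationError(
                f"consistency must be one of {CONSISTENCIES}, got {self.consistency!r}"
            )
        if not (self.bolus_volume_ml > 0 and math.isfinite(self.bolus_volume_ml)):
            raise ValidationError(
                f"bolus_volume_ml must be positive, got {self.bolus_volume_ml}"
            )


@dataclass(frozen=True)
class SwallowRecording:
    """One annotated swallow: metadata plus frames sorted by frame index."""

    meta: RecordingMeta
    frames: tuple[FrameLandmarks, ...]

    def __init__(self, meta: RecordingMeta, frames: Iterable[FrameLandmarks]):
        frames = tuple(sorted(frames, key=lambda f: f.frame_index))
        if len(frames) < 2:
            raise ValidationError(
                f"recording {meta.recording_id!r} needs at least 2 frames, "
                f"got {len(frames)}"
            )
        indices = [f.frame_index for f in frames]
        if len(set(indices)) != len(indices):
            dup = sorted({i for i in indices if indices.count(i) > 1})
            raise ValidationError(
                f"recording {meta.recording_id!r} has duplicate frame indices {dup}"
            )
        object.__setattr__(self, "meta", meta)
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def complete_frames(self) -> tuple[FrameLandmarks, ...]:
        """Frames where all six landmarks are present."""
        return tuple(f for f in self.frames if f.is_complete)


# ---------------------------------------------------------------------------
# File I/O

_META_FIELDS = (
    ("recording_id", str),
    ("fps", float),
    ("mm_per_pixel", float),
    ("pas", int),
    ("mbsimp_residue", int),
    ("consistency", str),
    ("bolus_volume_ml", float),
)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "json"):
            raise ValidationError(f"format must be 'csv' or 'json', got {format!r}")
        return format
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix == ".json":
        return "json"
    raise ValidationError(
        f"cannot infer annotation format from suffix {suffix!r}; pass format="
    )


def write_recording(
    recording: SwallowRecording, path: str | Path, format: str | None = None
) -> None:
    """Write a recording so that :func:`read_recording` round-trips it."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        _write_csv(recording, path)
    else:
        _write_json(recording, path)


def _write_csv(recording: SwallowRecording, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# {_CSV_MAGIC} v1\n")
        for name, _ in _META_FIELDS:
            fh.write(f"# {name}={getattr(recording.meta, name)!s}\n")
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "landmark", "x", "y"])
        for frame in recording.frames:
            for name in LANDMARK_NAMES:
                p = frame.get(name)
                if p is None:
                    writer.writerow([frame.frame_index, name, "", ""])
                else:
                    writer.writerow([frame.frame_index, name, repr(p.x), repr(p.y)])


def _write_json(recording: SwallowRecording, path: Path) -> None:
    doc = {
        "schema": _JSON_SCHEMA,
        "version": 1,
        "meta": asdict(recording.meta),
        "frames": [
            {
                "frame_index": frame.frame_index,
                **{
                    name: (
                        None
                        if frame.get(name) is None
                        else [frame.get(name).x, frame.get(name).y]
                    )
                    for name in LANDMARK_NAMES
                },
            }
            for frame in recording.frames
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_recording(path: str | Path, format: str | None = None) -> SwallowRecording:
    """Read and validate an annotation file (CSV or JSON, inferred by suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    return _read_csv(path) if fmt == "csv" else _read_json(path)


def _parse_meta(raw: dict[str, str], where: str) -> RecordingMeta:
    kwargs = {}
    for name, typ in _META_FIELDS:
        if name not in raw:
            raise ParseError(f"{where}: missing metadata field {name!r}")
        try:
            value = typ(raw[name])
            if typ is int and isinstance(raw[name], str) and "." in raw[name]:
                raise ValueError
        except (TypeError, ValueError):
            raise ParseError(
                f"{where}: metadata field {name!r} has invalid value {raw[name]!r}"
            ) from None
        kwargs[name] = value
    return RecordingMeta(**kwargs)


def _read_csv(path: Path) -> SwallowRecording:
    raw_meta: dict[str, str] = {}
    frames: dict[int, dict[str, PixelPoint | None]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        stripped = line.lstrip("# ").strip()
        if "=" in stripped:
            key, _, value = stripped.partition("=")
            raw_meta[key.strip()] = value.strip()
    meta = _parse_meta(raw_meta, f"{path.name} header")
    reader = csv.reader(lines[body_start:])
    header = next(reader, None)
    if header is None or [h.strip() for h in header] != ["frame_index", "landmark", "x", "y"]:
        raise ParseError(f"{path.name}: expected header 'frame_index,landmark,x,y'")
    for rowno, row in enumerate(reader, start=body_start + 2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != 4:
            raise ParseError(f"{path.name} row {rowno}: expected 4 columns, got {len(row)}")
        idx_s, name, xs, ys = (c.strip() for c in row)
        try:
            idx = int(idx_s)
        except ValueError:
            raise ParseError(
                f"{path.name} row {rowno}: bad frame_index {idx_s!r}"
            ) from None
        if name not in LANDMARK_NAMES:
            raise ParseError(f"{path.name} row {rowno}: unknown landmark {name!r}")
        if (xs == "") != (ys == ""):
            raise ParseError(
                f"{path.name} row {rowno}: landmark {name!r} has one empty coordinate"
            )
        if xs == "":
            point = None
        else:
            try:
                point = PixelPoint(float(xs), float(ys))
            except ValueError:
                raise ParseError(
                    f"{path.name} row {rowno}: bad coordinates ({xs!r}, {ys!r})"
                ) from None
        slot = frames.setdefault(idx, {})
        if name in slot:
            raise ParseError(
                f"{path.name} row {rowno}: duplicate landmark {name!r} in frame {idx}"
            )
        slot[name] = point
    frame_objs = [
        FrameLandmarks(frame_index=idx, **landmarks) for idx, landmarks in frames.items()
    ]
    return SwallowRecording(meta=meta, frames=frame_objs)


def _read_json(path: Path) -> SwallowRecording:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path.name}: invalid JSON ({exc})") from None
    if not isinstance(doc, dict) or doc.get("schema") != _JSON_SCHEMA:
        raise ParseError(f"{path.name}: not a {_JSON_SCHEMA} document")
    meta = _parse_meta(doc.get("meta", {}), f"{path.name} meta")
    frames = []
    for i, entry in enumerate(doc.get("frames", [])):
        if "frame_index" not in entry:
            raise ParseError(f"{path.name} frames[{i}]: missing frame_index")
        kwargs: dict = {}
        for name in LANDMARK_NAMES:
            value = entry.get(name)
            if value is None:
                kwargs[name] = None
            else:
                if not (isinstance(value, (list, tuple)) and len(value) == 2):
                    raise ParseError(
                        f"{path.name} frames[{i}]: landmark {name!r} must be "
                        f"[x, y] or null"
                    )
                kwargs[name] = PixelPoint(float(value[0]), float(value[1]))
        frames.append(FrameLandmarks(frame_index=int(entry["frame_index"]), **kwargs))
    return SwallowRecording(meta=meta, frames=frames)


# ---------------------------------------------------------------------------
# Exclusion rule

@dataclass(frozen=True)
class ValidationResult:
    """Outcome of the landmark-recognition exclusion rule."""

    included: bool
    reason: str | None
    recording: SwallowRecording | None
    n_frames_dropped: int = 0


def validate_recording(
    recording: SwallowRecording,
    max_missing_fraction: float = 0.2,
    min_complete_frames: int = 10,
) -> ValidationResult:
    """Apply the unrecognizable-landmark exclusion rule.

    A recording is excluded when the fraction of frames missing any of the
    six landmarks exceeds ``max_missing_fraction``, or when fewer than
    ``min_complete_frames`` complete frames remain; otherwise the incomplete
    frames are dropped and the reduced recording returned.  Deterministic and
    independent of frame order.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValidationError(
            f"max_missing_fraction must be in [0, 1], got {max_missing_fraction}"
        )
    total = recording.n_frames
    complete = recording.complete_frames()
    missing_fraction = 1.0 - len(complete) / total
    if missing_fraction > max_missing_fraction:
        return ValidationResult(
            included=False,
            reason=(
                f"{missing_fraction:.3f} of frames miss a landmark "
                f"(limit {max_missing_fraction})"
            ),
            recording=None,
            n_frames_dropped=total - len(complete),
        )
    if len(complete) < max(min_complete_frames, 2):
        return ValidationResult(
            included=False,
            reason=(
                f"only {len(complete)} complete frames "
                f"(minimum {max(min_complete_frames, 2)})"
            ),
            recording=None,
            n_frames_dropped=total - len(complete),
        )
    reduced = (
        recording
        if len(complete) == total
        else SwallowRecording(meta=recording.meta, frames=complete)
    )
    return ValidationResult(
        included=True,
        reason=None,
        recording=reduced,
        n_frames_dropped=total - len(complete),
    )
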