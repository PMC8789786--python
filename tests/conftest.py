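import numpy as np
import pytest

from hyokin import (
    ExtractionConfig,
    FrameLandmarks,
    PixelPoint,
    RecordingMeta,
    SceneModel,
    SwallowRecording,
)


@pytest.fixture
def axis_frame() -> FrameLandmarks:
    """Axis-aligned vertebral column: C4 at (100,100), C3 above, C5 below,
    mandible up-left (anterior in a left-facing image)."""
    return FrameLandmarks(
        frame_index=0,
        c2=PixelPoint(100.0, 80.0),
        c3=PixelPoint(100.0, 90.0),
        c4=PixelPoint(100.0, 100.0),
        c5=PixelPoint(100.0, 110.0),
        hyoid=PixelPoint(90.0, 105.0),
        mandible=PixelPoint(60.0, 70.0),
    )


def make_recording(
    n_frames: int = 60,
    hyoid_path=None,
    missing: dict | None = None,
    fps: float = 30.0,
    mm_per_pixel: float = 0.5,
    **meta_kwargs,
) -> SwallowRecording:
    """Recording with a static spine and an optional per-frame hyoid path.

    ``hyoid_path`` maps frame index -> (x, y) pixel position (default static);
    ``missing`` maps frame index -> iterable of landmark names to drop.
    """
    missing = missing or {}
    frames = []
    for i in range(n_frames):
        hx, hy = (90.0, 105.0) if hyoid_path is None else hyoid_path(i)
        landmarks = {
            "c2": PixelPoint(100.0, 80.0),
            "c3": PixelPoint(100.0, 90.0),
            "c4": PixelPoint(100.0, 100.0),
            "c5": PixelPoint(100.0, 110.0),
            "hyoid": PixelPoint(hx, hy),
            "mandible": PixelPoint(60.0, 70.0),
        }
        for name in missing.get(i, ()):
            landmarks[name] = None
        frames.append(FrameLandmarks(frame_index=i, **landmarks))
    meta = RecordingMeta(
        recording_id=meta_kwargs.pop("recording_id", "test"),
        fps=fps,
        mm_per_pixel=mm_per_pixel,
        **meta_kwargs,
    )
    return SwallowRecording(meta=meta, frames=frames)


@pytest.fixture
def quiet_scene() -> SceneModel:
    return SceneModel().quiet()


@pytest.fixture
def raw_config() -> ExtractionConfig:
    """Extraction without smoothing, for noise-free fixtures."""
    return ExtractionConfig(smoothing_window=1)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
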