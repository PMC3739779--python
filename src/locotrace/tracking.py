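"""Threshold-based blob tracker emulating a commercial video tracking system.

Detection semantics: the background level is estimated as the frame's modal
intensity; pixels deviating from it by more than ``detection_threshold``
("transparent background" mode) form the foreground.  Connected components
(8-connectivity) of at least 4 pixels are candidate animals; the largest is
returned.  A second, higher cut (``size_threshold``) on the same background
model serves the surface-area measurement, whose pixel counts convert to
mm^2 through a stage-specific calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .errors import LocotraceError, ValidationError
from .render import FrameStack
from .simulate import Trajectory

#: mm^2 per pixel of the surface ("size") measurement at each stage.  The
#: larval stage is excluded: at 6 dpf inter-individual pixel-size differences
#: are below the resolution of the measurement.
STAGE_SURFACE_CALIBRATION = {"1month": 2.23, "3months": 3.61}

MIN_COMPONENT_PX = 4


@dataclass(frozen=True)
class Detection:
    """One frame's blob-detection outcome (centroid in pixel coordinates)."""

    frame_index: int
    centroid: tuple[float, float] | None
    pixel_area: int
    found: bool

    def __post_init__(self):
        if not self.found and self.pixel_area != 0:
            raise ValidationError("a missing detection must have pixel_area 0")


@dataclass(frozen=True)
class TrackerConfig:
    detection_threshold: float = 11.0
    size_threshold: float = 117.0
    background_mode: str = "transparent"
    stage_calibration: dict = field(
        default_factory=lambda: dict(STAGE_SURFACE_CALIBRATION))

    def __post_init__(self):
        for name in ("detection_threshold", "size_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValidationError(f"{name} must be in [0, 255], got {v}")
        if any(v <= 0 for v in self.stage_calibration.values()):
            raise ValidationError("surface calibrations must be positive")


def modal_background(frame: np.ndarray) -> int:
    """Background level = modal intensity of the frame."""
    return int(np.bincount(np.asarray(frame, dtype=np.uint8).ravel(),
                           minlength=256).argmax())


def detect_blob(frame: np.ndarray, config: TrackerConfig,
                frame_index: int = 0, threshold: float | None = None) -> Detection:
    """Largest supra-threshold connected component of one grayscale frame.

    Absence of any component of >= 4 pixels is a valid result
    (``found=False``), not an error.
    """
    frame = np.asarray(frame)
    if frame.size == 0:
        raise ValidationError("frame is empty")
    cut = config.detection_threshold if threshold is None else threshold
    bg = modal_background(frame)
    mask = np.abs(frame.astype(np.int16) - bg) > cut
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return Detection(frame_index, None, 0, False)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    best = int(counts.argmax())
    if counts[best] < MIN_COMPONENT_PX:
        return Detection(frame_index, None, 0, False)
    rr, cc = np.nonzero(labels == best)
    # pixel-centre convention, matching the renderer
    centroid = (float(cc.mean() + 0.5), float(rr.mean() + 0.5))
    return Detection(frame_index, centroid, int(counts[best]), True)


def track(frames: FrameStack, config: TrackerConfig,
          animal_id: str = "animal0", strain_name: str = "", stage: str = "6dpf") -> Trajectory:
    """Per-frame blob detection -> trajectory in mm.

    Frames with no detection carry the last known position forward and are
    flagged; leading undetected frames take the first detected position.
    """
    n = frames.n_frames
    if n == 0:
        raise LocotraceError("no animal detected: empty frame stack")
    H = frames.shape[0]
    mmpp = frames.mm_per_pixel
    ox, oy = frames.origin_mm
    positions = np.zeros((n, 2))
    flags = np.zeros(n, dtype=bool)
    last = None
    first_found = None
    for i in range(n):
        det = detect_blob(frames.frames[i], config, frame_index=i)
        if det.found:
            x_px, y_px = det.centroid
            pos = (ox + x_px * mmpp, oy + (H - y_px) * mmpp)
            if first_found is None:
                first_found = i
            last = pos
            positions[i] = pos
        else:
            flags[i] = True
            if last is not None:
                positions[i] = last
    if first_found is None:
        raise LocotraceError("no animal detected in any frame")
    positions[:first_found] = positions[first_found]
    arena = (frames.shape[1] * mmpp, frames.shape[0] * mmpp)
    return Trajectory(animal_id=animal_id, strain_name=strain_name, stage=stage,
                      fps=frames.fps, positions=positions, arena=arena, flags=flags)


def surface_detections(frames: FrameStack, config: TrackerConfig) -> list[Detection]:
    """Run blob detection with the surface ("size") threshold on every frame."""
    return [detect_blob(frames.frames[i], config, frame_index=i,
                        threshold=config.size_threshold)
            for i in range(frames.n_frames)]


def surface_area_mm2(detections: list[Detection], config: TrackerConfig,
                     stage: str) -> float:
    """Mean found pixel area x the stage calibration, in mm^2.

    Refuses ``stage="6dpf"``: the surface measurement is not resolved at the
    larval stage.
    """
    if stage not in config.stage_calibration:
        raise ValidationError(
            f"no surface calibration for stage {stage!r} "
            f"(available: {sorted(config.stage_calibration)})")
    areas = [d.pixel_area for d in detections if d.found]
    if not areas:
        raise LocotraceError("surface area undefined: zero found detections")
    return float(np.mean(areas) * config.stage_calibration[stage])
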