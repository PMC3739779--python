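"""Rasterize trajectories into synthetic grayscale frames.

Synthetic stand-in for the behaviour-box video: each frame shows one filled
ellipse (2:1 aspect, oriented along the instantaneous heading) of pixel
area ~ body area / mm_per_pixel^2 on a uniform background, plus additive
uniform integer noise whose amplitude stays below the detection threshold,
so the thresholded mask is stable frame to frame and a stationary fish
yields a bit-identical silhouette.

The camera field of view extends one body length beyond the arena on every
side (``origin_mm`` records the mm position of the pixel grid's lower-left
corner, which is negative), so the silhouette is never clipped by the frame
edge even when the animal touches a wall.  Pixel (r, c) covers the square
[c, c+1) x [r, r+1); its centre sits at mm position
x = origin_x + (c + 0.5) * mm_per_pixel, y = origin_y + (H - r - 0.5) *
mm_per_pixel (y axis up, arena origin at its lower-left corner).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .profiles import StrainProfile
from .simulate import Trajectory


@dataclass
class FrameStack:
    """Ordered grayscale frames plus the geometry needed to invert them."""

    frames: np.ndarray          # (n, H, W) uint8
    mm_per_pixel: float
    background_level: int
    fish_level: int
    fps: float = 25.0
    origin_mm: tuple[float, float] = (0.0, 0.0)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return tuple(self.frames.shape[1:])


def render_frames(trajectory: Trajectory, profile: StrainProfile,
                  mm_per_pixel: float, seed: int | np.random.SeedSequence,
                  background_level: int = 200, fish_level: int = 80,
                  noise_amplitude: int = 4) -> FrameStack:
    """Render one trajectory as a stack of synthetic camera frames."""
    if mm_per_pixel <= 0:
        raise ValidationError("mm_per_pixel must be positive")
    rng = np.random.default_rng(seed)
    w_mm, h_mm = trajectory.arena

    area_mm2 = float(np.clip(rng.normal(profile.body_area_mean, profile.body_area_sd),
                             0.25 * profile.body_area_mean, 4.0 * profile.body_area_mean))
    area_px = area_mm2 / mm_per_pixel ** 2
    if area_px < 4:
        raise ValidationError(
            f"body area {area_mm2:.3g} mm^2 is under 4 pixels at "
            f"{mm_per_pixel} mm/pixel; use a finer calibration")
    # 2:1 ellipse, area = pi * a * b with b = a / 2
    a_mm = np.sqrt(2.0 * area_mm2 / np.pi)
    b_mm = a_mm / 2.0
    if 2 * a_mm > min(w_mm, h_mm):
        raise ValidationError("fish is larger than the arena")

    pad_px = int(np.ceil(a_mm / mm_per_pixel)) + 2
    pad_mm = pad_px * mm_per_pixel
    W = int(np.ceil(w_mm / mm_per_pixel)) + 2 * pad_px
    H = int(np.ceil(h_mm / mm_per_pixel)) + 2 * pad_px
    origin = (-pad_mm, -pad_mm)

    n = trajectory.length
    if n == 0:
        return FrameStack(np.zeros((0, H, W), dtype=np.uint8), mm_per_pixel,
                          background_level, fish_level, trajectory.fps, origin)

    headings = _frame_headings(trajectory)
    frames = np.empty((n, H, W), dtype=np.uint8)
    noise = rng.integers(-noise_amplitude, noise_amplitude + 1, size=(n, H, W))
    for i in range(n):
        img = np.full((H, W), background_level, dtype=np.int16)
        pos = trajectory.positions[i] - np.asarray(origin)
        mask = _ellipse_mask(pos, headings[i], a_mm, b_mm, mm_per_pixel, H, W)
        img[mask] = fish_level
        frames[i] = np.clip(img + noise[i], 0, 255).astype(np.uint8)
    return FrameStack(frames, mm_per_pixel, background_level, fish_level,
                      trajectory.fps, origin)


def _frame_headings(trajectory: Trajectory) -> np.ndarray:
    """Heading per frame from the last non-zero displacement (0 initially)."""
    n = trajectory.length
    headings = np.zeros(n)
    if n < 2:
        return headings
    d = np.diff(trajectory.positions, axis=0)
    ang = np.arctan2(d[:, 1], d[:, 0])
    moving = np.linalg.norm(d, axis=1) > 0
    current = 0.0
    for i in range(1, n):
        if moving[i - 1]:
            current = ang[i - 1]
        headings[i] = current
    headings[0] = headings[1] if n > 1 else 0.0
    return headings


def _ellipse_mask(pos_mm: np.ndarray, heading: float, a_mm: float, b_mm: float,
                  mm_per_pixel: float, H: int, W: int) -> np.ndarray:
    """Pixels whose centre lies inside the oriented ellipse."""
    cx, cy = float(pos_mm[0]), float(pos_mm[1])
    r_lo = max(int((H - (cy + a_mm) / mm_per_pixel) - 2), 0)
    r_hi = min(int((H - (cy - a_mm) / mm_per_pixel) + 2), H)
    c_lo = max(int(((cx - a_mm) / mm_per_pixel) - 2), 0)
    c_hi = min(int(((cx + a_mm) / mm_per_pixel) + 2), W)
    rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
    px = (cc + 0.5) * mm_per_pixel
    py = (H - rr - 0.5) * mm_per_pixel
    dx, dy = px - cx, py - cy
    ct, st = np.cos(heading), np.sin(heading)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a_mm) ** 2 + (v / b_mm) ** 2 <= 1.0
    mask = np.zeros((H, W), dtype=bool)
    mask[r_lo:r_hi, c_lo:c_hi] = inside
    return mask


def save_frames(stack: FrameStack, path: str | Path) -> None:
    """Write the stack as a multi-page TIFF (or PNG sequence if a directory)."""
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile

        tifffile.imwrite(path, stack.frames, photometric="minisblack")
    else:
        path.mkdir(parents=True, exist_ok=True)
        for i in range(stack.n_frames):
            iio.imwrite(path / f"frame_{i:06d}.png", stack.frames[i])


def load_frames(path: str | Path, mm_per_pixel: float, background_level: int = 200,
                fish_level: int = 80, fps: float = 25.0,
                origin_mm: tuple[float, float] = (0.0, 0.0)) -> FrameStack:
    """Read a multi-page TIFF or a directory of PNG frames."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.png"))
        frames = np.stack([iio.imread(f) for f in files])
    else:
        frames = np.asarray(iio.imread(path))
        if frames.ndim == 2:
            frames = frames[None]
    return FrameStack(frames.astype(np.uint8), mm_per_pixel, background_level,
                      fish_level, fps, origin_mm)
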