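"""Locomotion quantities: activity segmentation, binned distance, summaries.

The metric definitions follow the behavioural-tracking convention: swimming
time is the total duration of frame intervals whose displacement exceeds a
movement threshold, resting time is its exact complement within the session,
and the mean (active) speed is total distance divided by swimming time, not
by the recording duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binseries import BinSeries
from .errors import ValidationError
from .profiles import SessionSpec
from .simulate import Trajectory

#: Default movement threshold in mm per frame.  At 25 fps this is 0.05 mm/s,
#: below the slowest within-bout displacement of the packaged profiles
#: (larval sculling, ~0.1 mm/s) and above the stationary-frame displacement
#: of the synthetic tracker (exactly zero), so "no movement detected" frames
#: are the genuine rest bouts.  Configurable in every entry point.
DEFAULT_MOVE_THRESHOLD_MM = 0.002

MM_PER_CM = 10.0


@dataclass
class ActivityMask:
    """Per-frame moving/not-moving classification of a trajectory.

    ``interval`` holds one boolean per frame interval (length n_frames - 1);
    ``frame`` one per frame, the first frame inheriting the first interval's
    state.
    """

    interval: np.ndarray
    move_threshold: float
    fps: float

    @property
    def frame(self) -> np.ndarray:
        if len(self.interval) == 0:
            return np.zeros(0, dtype=bool)
        return np.concatenate([[self.interval[0]], self.interval])

    @property
    def active_time(self) -> float:
        return float(self.interval.sum() / self.fps)


@dataclass
class LocomotionSummary:
    """Per-animal totals for one session (reported in cm / s / cm/s)."""

    total_distance_cm: float
    swim_time_s: float
    rest_time_s: float
    mean_speed_cm_s: float
    zero_activity: bool = False

    @property
    def session_duration_s(self) -> float:
        return self.swim_time_s + self.rest_time_s


def segment_activity(trajectory: Trajectory,
                     move_threshold: float = DEFAULT_MOVE_THRESHOLD_MM) -> ActivityMask:
    """Classify each frame interval as moving (displacement > threshold) or not."""
    if trajectory.length < 2:
        raise ValidationError("trajectory must have at least 2 frames")
    disp = trajectory.step_lengths()
    return ActivityMask(interval=disp > move_threshold,
                        move_threshold=move_threshold, fps=trajectory.fps)


def bin_distances(trajectory: Trajectory, mask: ActivityMask,
                  integration_period: float) -> BinSeries:
    """Sum frame displacements and active time into integration bins.

    All frame displacements contribute to bin distance (so bin sums conserve
    total path length); the mask only gates active time.
    """
    if len(mask.interval) != trajectory.length - 1:
        raise ValidationError("mask length does not match trajectory")
    n = trajectory.length - 1
    duration = n / trajectory.fps
    n_bins = duration / integration_period
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValidationError(
            f"session duration {duration} s is not a multiple of "
            f"integration period {integration_period} s")
    n_bins = round(n_bins)
    per_bin = round(integration_period * trajectory.fps)
    disp = trajectory.step_lengths()
    idx = np.arange(n) // per_bin
    distance = np.bincount(idx, weights=disp, minlength=n_bins)
    active = np.bincount(idx, weights=mask.interval.astype(float), minlength=n_bins) / trajectory.fps
    return BinSeries(animal_id=trajectory.animal_id,
                     integration_period=float(integration_period),
                     bin_start=np.arange(n_bins) * float(integration_period),
                     distance=distance, active_time=active)


def summarize(bins: BinSeries, session: SessionSpec) -> LocomotionSummary:
    """Reduce a bin series to the session totals.

    mean speed = total distance / swimming time; a zero-activity animal is
    reported with speed 0 and an explicit flag rather than dropped.
    """
    if abs(bins.duration - session.duration) > 1e-6:
        raise ValidationError(
            f"bin series covers {bins.duration} s, session lasts {session.duration} s")
    total_mm = float(bins.distance.sum())
    swim = float(bins.active_time.sum())
    rest = session.duration - swim
    total_cm = total_mm / MM_PER_CM
    # below ~a picosecond of activity the speed quotient is meaningless:
    # report the animal as inactive instead of overflowing
    if swim > 1e-12:
        return LocomotionSummary(total_cm, swim, rest, total_cm / swim, zero_activity=False)
    return LocomotionSummary(total_cm, 0.0, session.duration, 0.0, zero_activity=True)


def timecourse(series: list[BinSeries]) -> pd.DataFrame:
    """Group mean +/- SEM distance per bin across animals.

    Returns a DataFrame indexed by bin start with columns ``mean``, ``sem``
    and ``n``.  All animals must share the same bin grid.
    """
    if len(series) < 2:
        raise ValidationError("timecourse needs at least 2 animals")
    grid = series[0].bin_start
    for s in series[1:]:
        if not np.array_equal(s.bin_start, grid):
            raise ValidationError(
                f"ragged bin grids: animal {s.animal_id!r} does not match "
                f"animal {series[0].animal_id!r}")
    mat = np.vstack([s.distance for s in series])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(n)
    return pd.DataFrame({"mean": mean, "sem": sem, "n": n}, index=pd.Index(grid, name="bin_start_s"))
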