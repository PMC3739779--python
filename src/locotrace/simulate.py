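"""Stochastic burst-and-glide trajectory generator.

The swimmer is an alternating renewal process: rest bouts of zero
displacement (exponential durations, mean ``rest_bout_mean``) alternate with
swim bouts (exponential, mean ``swim_bout_mean``) during which per-frame
speed is drawn around ``cruise_speed_mean`` and the heading performs a
persistent random walk.  A renewal process with mean rate ``burst_rate``
(refractory dead time plus an exponential gap, so burst episodes cannot
re-fire immediately) superimposes bursts of ``burst_duration`` seconds at
``burst_speed_mean``; a burst overrides the bout state, so a burst landing
in a rest bout briefly interrupts it.  Positions reflect specularly at the arena walls, which
preserves per-step path length.

The bout process is started in its stationary regime (initial state drawn
with the stationary active probability; exponential memorylessness makes the
first duration the correct residual), so the expected active fraction of a
session equals ``swim_bout_mean / (swim_bout_mean + rest_bout_mean)``.

Trajectories sample positions at ``fps`` from t = 0 to t = duration
inclusive, so a session of T seconds yields ``T * fps`` frame intervals and
``T * fps + 1`` positions; interval i covers [i/fps, (i+1)/fps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .profiles import SessionSpec, StrainProfile, check_stage_agreement

#: Wrapped-normal turn-increment SD (radians per moving frame) per stage.
#: Larvae reorient sharply between slow sculling frames; adults cruise with
#: straighter, more persistent headings.  Irrelevant to path length.
STAGE_TURN_SD_RAD = {"6dpf": 0.9, "1month": 0.35, "3months": 0.25}


@dataclass
class Trajectory:
    """Centroid time series at a fixed frame rate, positions in mm.

    ``positions`` has shape (n_frames, 2) with the origin at the arena's
    lower-left corner.  ``active_truth`` is the generative ground truth, one
    boolean per frame interval (swim bout or burst), carried along so that
    activity segmentation can be validated against the schedule that
    produced the data.  ``flags`` marks frames whose position was not
    observed directly (used by the tracker for carried-forward frames).
    """

    animal_id: str
    strain_name: str
    stage: str
    fps: float
    positions: np.ndarray
    arena: tuple[float, float]
    active_truth: np.ndarray | None = None
    flags: np.ndarray | None = None

    @property
    def length(self) -> int:
        return int(self.positions.shape[0])

    @property
    def duration(self) -> float:
        return (self.length - 1) / self.fps

    def step_lengths(self) -> np.ndarray:
        """Per-interval displacement magnitudes (mm)."""
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)

    def path_length(self) -> float:
        return float(self.step_lengths().sum())


def animal_seed(master_seed: int, animal_index: int) -> np.random.SeedSequence:
    """Fixed hash of (master seed, animal index) -> independent seed."""
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(animal_index),))


def _bout_states(rng: np.random.Generator, profile: StrainProfile,
                 interval_starts: np.ndarray, duration: float) -> np.ndarray:
    """Boolean swim/rest state per frame interval (stationary start)."""
    mu_s, mu_r = profile.swim_bout_mean, profile.rest_bout_mean
    start_active = rng.random() < profile.active_fraction
    boundaries = [0.0]
    states = []
    state = bool(start_active)
    t = 0.0
    while t < duration:
        mean = mu_s if state else mu_r
        d = rng.exponential(mean) if mean > 0 else 0.0
        d = max(d, 1e-12)
        t += d
        boundaries.append(t)
        states.append(state)
        state = not state
    boundaries = np.asarray(boundaries)
    states = np.asarray(states, dtype=bool)
    idx = np.searchsorted(boundaries, interval_starts, side="right") - 1
    idx = np.clip(idx, 0, len(states) - 1)
    return states[idx]


#: Refractory dead time between burst initiations, seconds.  Burst episodes
#: do not re-fire immediately; inter-burst gaps are refractory + exponential,
#: a dead-time renewal process whose mean rate is ``burst_rate``.
BURST_REFRACTORY_S = 8.0


def _burst_mask(rng: np.random.Generator, profile: StrainProfile,
                interval_starts: np.ndarray, duration: float) -> np.ndarray:
    """Boolean burst coverage per frame interval (dead-time renewal arrivals)."""
    rate_per_s = profile.burst_rate / 60.0
    mask = np.zeros(interval_starts.shape, dtype=bool)
    if rate_per_s <= 0:
        return mask
    mean_gap = 1.0 / rate_per_s
    exp_mean = max(mean_gap - BURST_REFRACTORY_S, 0.0)
    dead = min(BURST_REFRACTORY_S, mean_gap)
    t = 0.0
    while True:
        t += dead + (rng.exponential(exp_mean) if exp_mean > 0 else 0.0)
        if t >= duration:
            break
        lo = np.searchsorted(interval_starts, t, side="right") - 1
        hi = np.searchsorted(interval_starts, t + profile.burst_duration, side="left")
        mask[max(lo, 0):hi] = True
    return mask


def simulate_trajectory(profile: StrainProfile, session: SessionSpec,
                        seed: int | np.random.SeedSequence,
                        animal_id: str = "animal0") -> Trajectory:
    """Simulate one session for one animal.  Same seed => identical output."""
    check_stage_agreement(profile, session)
    if session.duration <= 0:
        raise ValidationError("session duration must be positive")
    rng = np.random.default_rng(seed)
    n = session.n_intervals
    dt = 1.0 / session.fps
    interval_starts = np.arange(n) * dt

    swim = _bout_states(rng, profile, interval_starts, session.duration)
    burst = _burst_mask(rng, profile, interval_starts, session.duration)

    # Per-interval speed in mm/s: cruise draws are clipped symmetrically at
    # +/- 2.5 SD (mean-preserving) and kept strictly positive; bursts override.
    cruise_mm = 10.0 * profile.cruise_speed_mean
    sd_mm = 10.0 * profile.cruise_speed_sd
    burst_mm = 10.0 * profile.burst_speed_mean
    draws = rng.normal(cruise_mm, sd_mm, size=n)
    lo = max(cruise_mm - 2.5 * sd_mm, 1e-9)
    hi = cruise_mm + 2.5 * (cruise_mm - lo) / 2.5  # symmetric about the mean
    speed = np.clip(draws, lo, hi)
    speed[~swim] = 0.0
    speed[burst] = burst_mm
    active = swim | burst

    # Persistent random-walk heading; frozen while at rest.
    turn_sd = STAGE_TURN_SD_RAD[profile.age_stage]
    turns = rng.normal(0.0, turn_sd, size=n)
    turns[~active] = 0.0
    heading = rng.uniform(0.0, 2.0 * np.pi) + np.cumsum(turns)

    steps = speed * dt
    dx = steps * np.cos(heading)
    dy = steps * np.sin(heading)

    w, h = profile.arena_width, profile.arena_height
    x0 = rng.uniform(0.1 * w, 0.9 * w)
    y0 = rng.uniform(0.1 * h, 0.9 * h)
    x = _reflect(np.concatenate([[x0], x0 + np.cumsum(dx)]), w)
    y = _reflect(np.concatenate([[y0], y0 + np.cumsum(dy)]), h)

    positions = np.column_stack([x, y])
    return Trajectory(animal_id=animal_id, strain_name=profile.strain_name,
                      stage=profile.age_stage, fps=session.fps,
                      positions=positions, arena=(w, h), active_truth=active)


def _reflect(u: np.ndarray, width: float) -> np.ndarray:
    """Fold unbounded coordinates into [0, width] by specular reflection.

    Folding the cumulative coordinate with a period-2W triangle wave is
    exactly specular reflection of the underlying piecewise-linear motion.
    """
    m = np.mod(u, 2.0 * width)
    return np.where(m <= width, m, 2.0 * width - m)
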