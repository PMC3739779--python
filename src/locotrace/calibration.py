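"""Profile calibration: moment matching plus bisection on the burst rate.

The packaged profiles are fitted so that simulated cohort means of the
*measured* pipeline quantities (total distance, swimming time, fast-swim
event count) land on their per-strain targets.  The procedure is:

1. closed-form moment matching for the bout means: swimming time per hour
   ~ 3600 x active fraction, with the active fraction
   mu_swim / (mu_swim + mu_rest) and the rest-bout mean held at a
   stage-typical value;
2. a closed-form start for the speed scale: distance = swimming time x mean
   active speed, split between the within-bout baseline and the burst
   component;
3. deterministic bisection on ``burst_rate`` against the simulated mean
   event count (when an event-count target exists), interleaved with
   multiplicative refinement of the speed scale and active fraction against
   the simulated means, under fixed seeds.

Everything here is deterministic given (targets, seeds); it is run once to
produce the YAML files under ``data/profiles`` and kept so the fits are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pipeline import run_fastswim_assay, run_locomotion_assay
from .profiles import StrainProfile, locomotion_session


@dataclass(frozen=True)
class CalibrationTargets:
    """Cohort-mean targets for one strain x stage."""

    distance_cm: float          # per 60-minute session
    swim_time_s: float          # per 60-minute session
    n_events: float | None = None  # per 5-minute session (window rule)


def measured_means(profile: StrainProfile, n_animals: int, master_seed: int,
                   with_events: bool) -> dict[str, float]:
    """Simulated cohort means of the pipeline quantities."""
    summary, _ = run_locomotion_assay(profile, n_animals, master_seed)
    out = {"distance_cm": float(summary["total_distance_cm"].mean()),
           "swim_time_s": float(summary["swim_time_s"].mean())}
    if with_events:
        fs = run_fastswim_assay(profile, n_animals, master_seed)
        out["n_events"] = float(fs["n_events"].mean())
    return out


def initial_profile(strain: str, stage: str, targets: CalibrationTargets,
                    rest_bout_mean: float, baseline_speed_cm_s: float,
                    baseline_speed_sd: float, burst_rate: float,
                    burst_speed_cm_s: float, burst_duration: float,
                    body_area_mean: float, body_area_sd: float,
                    arena: tuple[float, float]) -> StrainProfile:
    """Closed-form moment-matching start for the iterative fit."""
    f = min(targets.swim_time_s / 3600.0, 0.98)
    mu_swim = rest_bout_mean * f / (1.0 - f)
    return StrainProfile(
        strain_name=strain, age_stage=stage,
        rest_bout_mean=rest_bout_mean, swim_bout_mean=mu_swim,
        cruise_speed_mean=baseline_speed_cm_s, cruise_speed_sd=baseline_speed_sd,
        burst_rate=burst_rate, burst_speed_mean=burst_speed_cm_s,
        burst_duration=burst_duration,
        body_area_mean=body_area_mean, body_area_sd=body_area_sd,
        arena_width=arena[0], arena_height=arena[1])


def calibrate_profile(profile: StrainProfile, targets: CalibrationTargets,
                      n_animals: int = 120, master_seed: int = 20130809,
                      n_rounds: int = 4, scale_bursts: bool = True,
                      ) -> StrainProfile:
    """Iteratively nudge a profile onto its cohort-mean targets.

    ``scale_bursts=True`` treats the burst component as the main distance
    carrier (larval regime) and adjusts ``burst_speed_mean``; otherwise the
    within-bout cruise speed is adjusted (juvenile/adult regime).  When an
    event-count target is present the burst rate is bisected against the
    simulated event count each round.
    """
    for _ in range(n_rounds):
        if targets.n_events is not None:
            profile = _bisect_burst_rate(profile, targets.n_events, n_animals,
                                         master_seed)
        m = measured_means(profile, n_animals, master_seed, with_events=False)
        f = profile.active_fraction * min(max(
            targets.swim_time_s / m["swim_time_s"], 0.5), 2.0)
        f = min(f, 0.98)
        mu_swim = profile.rest_bout_mean * f / (1.0 - f)
        profile = replace(profile, swim_bout_mean=mu_swim)

        m = measured_means(profile, n_animals, master_seed, with_events=False)
        ratio = min(max(targets.distance_cm / m["distance_cm"], 0.25), 4.0)
        if scale_bursts:
            profile = replace(profile, burst_speed_mean=profile.burst_speed_mean * ratio)
        else:
            new_cruise = profile.cruise_speed_mean * ratio
            profile = replace(profile, cruise_speed_mean=new_cruise,
                              cruise_speed_sd=profile.cruise_speed_sd * ratio)
    return profile


def _bisect_burst_rate(profile: StrainProfile, target_events: float,
                       n_animals: int, master_seed: int,
                       lo: float = 0.5, hi: float | None = None,
                       n_steps: int = 9) -> StrainProfile:
    """Deterministic bisection of burst_rate on the simulated mean count.

    The count is increasing in the rate only while the mean inter-burst gap
    stays above the refractory dead time (beyond that, bursts pack onto
    adjacent bins and merge into fewer runs), so the bracket is capped below
    60 / refractory events per minute.
    """
    from .simulate import BURST_REFRACTORY_S

    if hi is None:
        hi = 0.9 * 60.0 / BURST_REFRACTORY_S
    def count(rate: float) -> float:
        fs = run_fastswim_assay(replace(profile, burst_rate=rate),
                                n_animals, master_seed)
        return float(fs["n_events"].mean())

    if count(lo) >= target_events:
        return replace(profile, burst_rate=lo)
    if count(hi) <= target_events:
        return replace(profile, burst_rate=hi)
    for _ in range(n_steps):
        mid = 0.5 * (lo + hi)
        if count(mid) < target_events:
            lo = mid
        else:
            hi = mid
    return replace(profile, burst_rate=0.5 * (lo + hi))
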