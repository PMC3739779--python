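"""End-to-end cohort runs: simulate -> segment -> bin -> summarize / score.

These helpers tie the simulator to the metric modules the way an assay is
actually run: one master seed, per-animal seeds derived by fixed hashing of
(master seed, assay, animal index), one 60-minute locomotion session and one
5-minute fast-swim session per animal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .binseries import BinSeries
from .errors import ValidationError
from .fastswim import count_fast_swim_events, event_speed
from .metrics import DEFAULT_MOVE_THRESHOLD_MM, bin_distances, segment_activity, summarize
from .profiles import SessionSpec, StrainProfile, fastswim_session, locomotion_session
from .simulate import simulate_trajectory

ASSAY_LOCOMOTION = 0
ASSAY_FASTSWIM = 1
ASSAY_SURFACE = 2


def derived_seed(master_seed: int, assay: int, animal_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed),
                                  spawn_key=(int(assay), int(animal_index)))


def run_locomotion_assay(profile: StrainProfile, n_animals: int, master_seed: int,
                         session: SessionSpec | None = None,
                         move_threshold: float = DEFAULT_MOVE_THRESHOLD_MM,
                         ) -> tuple[pd.DataFrame, list[BinSeries]]:
    """Simulate a cohort's locomotion sessions and summarize each animal.

    Returns (summary table, per-animal bin series).  Summary columns:
    animal_id, strain, stage, total_distance_cm, swim_time_s, rest_time_s,
    mean_speed_cm_s, zero_activity_flag.
    """
    if n_animals < 1:
        raise ValidationError("n_animals must be >= 1")
    session = session or locomotion_session(profile.age_stage)
    rows = []
    all_bins = []
    for i in range(n_animals):
        aid = f"{profile.strain_name}_{profile.age_stage}_{i:03d}"
        traj = simulate_trajectory(profile, session,
                                   derived_seed(master_seed, ASSAY_LOCOMOTION, i),
                                   animal_id=aid)
        mask = segment_activity(traj, move_threshold)
        bins = bin_distances(traj, mask, session.integration_period)
        s = summarize(bins, session)
        rows.append({"animal_id": aid, "strain": profile.strain_name,
                     "stage": profile.age_stage,
                     "total_distance_cm": s.total_distance_cm,
                     "swim_time_s": s.swim_time_s, "rest_time_s": s.rest_time_s,
                     "mean_speed_cm_s": s.mean_speed_cm_s,
                     "zero_activity_flag": s.zero_activity})
        all_bins.append(bins)
    return pd.DataFrame(rows), all_bins


def run_fastswim_assay(profile: StrainProfile, n_animals: int, master_seed: int,
                       rule: str = "window",
                       move_threshold: float = DEFAULT_MOVE_THRESHOLD_MM) -> pd.DataFrame:
    """Simulate 5-minute sessions and score fast-swim events per animal.

    Columns: animal_id, n_events, mean_event_speed_mm_s (NaN when no event).
    """
    if n_animals < 1:
        raise ValidationError("n_animals must be >= 1")
    session = fastswim_session(profile.age_stage)
    rows = []
    for i in range(n_animals):
        aid = f"{profile.strain_name}_{profile.age_stage}_fs{i:03d}"
        traj = simulate_trajectory(profile, session,
                                   derived_seed(master_seed, ASSAY_FASTSWIM, i),
                                   animal_id=aid)
        mask = segment_activity(traj, move_threshold)
        bins = bin_distances(traj, mask, session.integration_period)
        res = count_fast_swim_events(bins, rule=rule)
        speed = event_speed(res) if res.n_events else float("nan")
        rows.append({"animal_id": aid, "n_events": res.n_events,
                     "mean_event_speed_mm_s": speed})
    return pd.DataFrame(rows)


def draw_surfaces(profile: StrainProfile, n_animals: int, master_seed: int) -> np.ndarray:
    """Generative per-animal body surface areas (mm^2) for a cohort."""
    out = np.empty(n_animals)
    for i in range(n_animals):
        rng = np.random.default_rng(derived_seed(master_seed, ASSAY_SURFACE, i))
        out[i] = np.clip(rng.normal(profile.body_area_mean, profile.body_area_sd),
                         0.25 * profile.body_area_mean, 4.0 * profile.body_area_mean)
    return out
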