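import numpy as np
import pytest

from locotrace.profiles import SessionSpec, StrainProfile


@pytest.fixture
def larval_profile():
    """A small, fast-to-simulate larval-style profile (not a packaged one)."""
    return StrainProfile(
        strain_name="TEST", age_stage="6dpf",
        rest_bout_mean=2.0, swim_bout_mean=4.0,
        cruise_speed_mean=0.012, cruise_speed_sd=0.002,
        burst_rate=5.0, burst_speed_mean=2.0, burst_duration=1.2,
        body_area_mean=1.2, body_area_sd=0.1,
        arena_width=15.5, arena_height=15.5)


@pytest.fixture
def adult_profile():
    return StrainProfile(
        strain_name="TEST", age_stage="3months",
        rest_bout_mean=3.0, swim_bout_mean=20.0,
        cruise_speed_mean=4.5, cruise_speed_sd=0.8,
        burst_rate=4.0, burst_speed_mean=15.0, burst_duration=0.8,
        body_area_mean=390.0, body_area_sd=40.0,
        arena_width=245.0, arena_height=150.0)


@pytest.fixture
def short_session():
    return SessionSpec(duration=60.0, fps=25.0, integration_period=60.0, stage="6dpf")


def random_profile(rng: np.random.Generator, stage: str = "6dpf") -> StrainProfile:
    """Draw a structurally valid random profile for property tests."""
    from locotrace.profiles import STAGE_ARENAS_MM

    arena = STAGE_ARENAS_MM[stage]
    cruise = rng.uniform(0.01, 3.0)
    return StrainProfile(
        strain_name="RND", age_stage=stage,
        rest_bout_mean=rng.uniform(0.5, 10.0),
        swim_bout_mean=rng.uniform(0.5, 20.0),
        cruise_speed_mean=cruise, cruise_speed_sd=0.1 * cruise,
        burst_rate=rng.uniform(0.5, 7.0),
        burst_speed_mean=cruise * rng.uniform(2.0, 6.0),
        burst_duration=rng.uniform(0.2, 1.5),
        body_area_mean=(rng.uniform(1.0, 15.0) if stage == "6dpf"
                        else rng.uniform(50.0, 300.0)),
        body_area_sd=0.0,
        arena_width=arena[0], arena_height=arena[1])
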