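"""Strain x age generative profiles and recording-session specifications.

A :class:`StrainProfile` collects the parameters of the stochastic
burst-and-glide swimmer for one strain at one life stage: the alternating
rest/swim bout means, the within-bout cruise speed distribution, the Poisson
burst component, body size, and the arena footprint.  Packaged profiles for
six laboratory strains (AB, ABstrg, casper, EK, TU, WIK) at three stages
(6 dpf, 1 month, 3 months) ship as YAML under ``locotrace/data/profiles``.

A :class:`SessionSpec` describes a recording session: duration, frame rate
and the integration period over which the tracker sums distance (60 s for
6 dpf larvae, 300 s for juveniles and adults, 3 s for fast-swim sessions).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError, ValidationError

STAGES = ("6dpf", "1month", "3months")

#: Default arena footprint (width, height) in mm per stage.  The larval stage
#: uses one well of a 24-well plate, modelled as a 15.5 mm square footprint;
#: juveniles a 95 x 60 mm tank; adults a 245 x 150 mm tank.
STAGE_ARENAS_MM: dict[str, tuple[float, float]] = {
    "6dpf": (15.5, 15.5),
    "1month": (95.0, 60.0),
    "3months": (245.0, 150.0),
}

#: Integration period (s) used for locomotion sessions at each stage.
STAGE_INTEGRATION_S: dict[str, float] = {"6dpf": 60.0, "1month": 300.0, "3months": 300.0}

STRAINS = ("AB", "ABstrg", "casper", "EK", "TU", "WIK")


@dataclass(frozen=True)
class StrainProfile:
    """Generative parameters for one strain at one life stage.

    Speeds are in cm/s (the reporting unit); the simulator converts to mm
    internally.  ``burst_rate`` is in events per minute; bout means and the
    burst duration in seconds; body areas in mm^2; arena dimensions in mm.
    """

    strain_name: str
    age_stage: str
    rest_bout_mean: float
    swim_bout_mean: float
    cruise_speed_mean: float
    cruise_speed_sd: float
    burst_rate: float
    burst_speed_mean: float
    burst_duration: float
    body_area_mean: float
    body_area_sd: float
    arena_width: float
    arena_height: float

    def __post_init__(self):
        if self.age_stage not in STAGES:
            raise ValidationError(f"unknown age_stage {self.age_stage!r}; expected one of {STAGES}")
        positive = (
            "rest_bout_mean", "swim_bout_mean", "cruise_speed_mean", "burst_rate",
            "burst_speed_mean", "burst_duration", "body_area_mean",
            "arena_width", "arena_height",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in ("cruise_speed_sd", "body_area_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative, got {getattr(self, name)}")
        if not self.burst_speed_mean > self.cruise_speed_mean:
            raise ValidationError(
                "burst_speed_mean must exceed cruise_speed_mean "
                f"({self.burst_speed_mean} <= {self.cruise_speed_mean})"
            )

    @property
    def active_fraction(self) -> float:
        """Stationary probability of being inside a swim bout."""
        return self.swim_bout_mean / (self.swim_bout_mean + self.rest_bout_mean)

    def with_arena(self, width: float, height: float) -> "StrainProfile":
        return replace(self, arena_width=width, arena_height=height)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SessionSpec:
    """One recording session: duration, frame rate, integration period, stage."""

    duration: float
    fps: float = 25.0
    integration_period: float = 60.0
    stage: str = "6dpf"

    def __post_init__(self):
        if self.duration <= 0:
            raise ValidationError(f"duration must be positive, got {self.duration}")
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        n_bins = self.duration / self.integration_period
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ValidationError(
                f"duration {self.duration} s is not a multiple of the "
                f"integration period {self.integration_period} s"
            )
        n_frames = self.duration * self.fps
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValidationError(f"fps x duration = {n_frames} is not an integer frame count")

    @property
    def n_bins(self) -> int:
        return round(self.duration / self.integration_period)

    @property
    def n_intervals(self) -> int:
        """Number of frame intervals (frame count minus one)."""
        return round(self.duration * self.fps)


def locomotion_session(stage: str, duration: float = 3600.0, fps: float = 25.0) -> SessionSpec:
    """The 1-hour locomotion session with the stage's integration period."""
    return SessionSpec(duration=duration, fps=fps,
                       integration_period=STAGE_INTEGRATION_S[stage], stage=stage)


def fastswim_session(stage: str, duration: float = 300.0, fps: float = 25.0) -> SessionSpec:
    """The 5-minute fast-swim session with a 3-second integration period."""
    return SessionSpec(duration=duration, fps=fps, integration_period=3.0, stage=stage)


def check_stage_agreement(profile: StrainProfile, session: SessionSpec) -> None:
    if profile.age_stage != session.stage:
        raise ConfigurationError(
            f"profile stage {profile.age_stage!r} does not match session stage {session.stage!r}"
        )


_PROFILE_FIELDS = tuple(StrainProfile.__dataclass_fields__)


def load_profile_file(path: str | Path) -> StrainProfile:
    """Load one strain profile from a YAML document (keys = profile fields)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: expected a YAML mapping of profile fields")
    unknown = set(doc) - set(_PROFILE_FIELDS)
    if unknown:
        raise ValidationError(f"{path}: unknown profile keys {sorted(unknown)}")
    missing = set(_PROFILE_FIELDS) - set(doc)
    if missing:
        raise ValidationError(f"{path}: missing profile keys {sorted(missing)}")
    return StrainProfile(**doc)


def load_profile(strain: str, stage: str) -> StrainProfile:
    """Load a packaged strain x stage profile (e.g. ``load_profile("AB", "6dpf")``)."""
    if stage not in STAGES:
        raise ValidationError(f"unknown stage {stage!r}")
    name = f"{strain}_{stage}.yaml"
    root = resources.files("locotrace").joinpath("data/profiles")
    path = root.joinpath(name)
    if not path.is_file():
        raise ConfigurationError(f"no packaged profile {name}")
    with resources.as_file(path) as real:
        return load_profile_file(real)


def available_profiles() -> list[tuple[str, str]]:
    """(strain, stage) pairs with a packaged profile."""
    root = resources.files("locotrace").joinpath("data/profiles")
    out = []
    for entry in root.iterdir():
        if entry.name.endswith(".yaml"):
            strain, _, stage = entry.name[:-5].rpartition("_")
            out.append((strain, stage))
    return sorted(out)


def save_profile_file(path: str | Path, profile: StrainProfile, header: str = "") -> None:
    """Write a profile as a YAML document, optionally with a comment header."""
    text = yaml.safe_dump(profile.to_dict(), sort_keys=False)
    if header:
        commented = "\n".join(f"# {line}".rstrip() for line in header.splitlines())
        text = commented + "\n" + text
    Path(path).write_text(text, encoding="utf-8")


def stage_arena(stage: str) -> tuple[float, float]:
    return STAGE_ARENAS_MM[stage]
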