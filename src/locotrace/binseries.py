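"""Per-integration-bin distance and active time, plus its CSV dialect.

The :class:`BinSeries` is the unit a video-tracking export provides: for one
animal, per bin of the integration period, the distance swum (mm) and the
time spent moving (s).  The CSV dialect is::

    animal_id,bin_start_s,distance_mm,active_s

UTF-8, LF line endings, one row per bin, bin starts strictly increasing.
Distances are kept in mm to avoid cm/mm ambiguity; conversion to cm happens
at reporting time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ParseError, ValidationError

CSV_HEADER = ("animal_id", "bin_start_s", "distance_mm", "active_s")


@dataclass
class BinSeries:
    """Binned tracking export for one animal."""

    animal_id: str
    integration_period: float
    bin_start: np.ndarray
    distance: np.ndarray
    active_time: np.ndarray

    def __post_init__(self):
        self.bin_start = np.asarray(self.bin_start, dtype=float)
        self.distance = np.asarray(self.distance, dtype=float)
        self.active_time = np.asarray(self.active_time, dtype=float)
        if not (len(self.bin_start) == len(self.distance) == len(self.active_time)):
            raise ValidationError("bin_start, distance and active_time must have equal length")
        if self.integration_period <= 0:
            raise ValidationError("integration_period must be positive")
        if len(self.bin_start) and np.any(np.diff(self.bin_start) <= 0):
            raise ValidationError("bin starts must be strictly increasing")
        if np.any(self.distance < 0):
            raise ValidationError("distances must be non-negative")
        if np.any(self.active_time < -1e-9) or np.any(
                self.active_time > self.integration_period + 1e-9):
            raise ValidationError("active_time must lie in [0, integration_period]")

    @property
    def n_bins(self) -> int:
        return len(self.bin_start)

    @property
    def duration(self) -> float:
        return self.n_bins * self.integration_period

    def __eq__(self, other) -> bool:
        if not isinstance(other, BinSeries):
            return NotImplemented
        return (self.animal_id == other.animal_id
                and self.integration_period == other.integration_period
                and np.array_equal(self.bin_start, other.bin_start)
                and np.array_equal(self.distance, other.distance)
                and np.array_equal(self.active_time, other.active_time))


def write_binseries_csv(path: str | Path, bins: BinSeries | list[BinSeries]) -> None:
    """Write one or several animals' bin series in the documented dialect."""
    series = bins if isinstance(bins, list) else [bins]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for b in series:
            for t, d, a in zip(b.bin_start, b.distance, b.active_time):
                writer.writerow([b.animal_id, _fmt(t), _fmt(d), _fmt(a)])


def _fmt(x: float) -> str:
    return repr(float(x))


def read_binseries_table(path: str | Path) -> list[BinSeries]:
    """Parse a bin-series CSV; one :class:`BinSeries` per animal id.

    Raises :class:`ParseError` naming the offending line for a malformed
    header, non-numeric fields, negative distances or non-monotone bin
    starts.  The integration period is inferred from consecutive bin starts
    (a single-bin animal gets the file-wide period).
    """
    rows: dict[str, list[tuple[float, float, float]]] = {}
    order: list[str] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty file", line=1) from None
        if tuple(h.strip() for h in header) != CSV_HEADER:
            raise ParseError(f"malformed header {header!r}; expected {','.join(CSV_HEADER)}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ParseError(f"expected 4 fields, got {len(row)}", line=lineno)
            animal = row[0].strip()
            try:
                t, d, a = float(row[1]), float(row[2]), float(row[3])
            except ValueError:
                raise ParseError(f"non-numeric field in {row!r}", line=lineno) from None
            if d < 0:
                raise ParseError(f"negative distance {d}", line=lineno)
            if a < 0:
                raise ParseError(f"negative active time {a}", line=lineno)
            if animal in rows and rows[animal] and t <= rows[animal][-1][0]:
                raise ParseError(
                    f"bin start {t} not increasing for animal {animal!r}", line=lineno)
            if animal not in rows:
                rows[animal] = []
                order.append(animal)
            rows[animal].append((t, d, a))
    if not rows:
        raise ParseError("no data rows", line=2)

    periods = []
    for vals in rows.values():
        ts = [v[0] for v in vals]
        if len(ts) > 1:
            periods.append(ts[1] - ts[0])
    period = periods[0] if periods else 1.0

    out = []
    for animal in order:
        vals = rows[animal]
        out.append(BinSeries(
            animal_id=animal,
            integration_period=period,
            bin_start=np.array([v[0] for v in vals]),
            distance=np.array([v[1] for v in vals]),
            active_time=np.array([v[2] for v in vals]),
        ))
    return out


def read_binseries_csv(path: str | Path) -> BinSeries:
    """Parse a single-animal bin-series CSV (round-trip partner of write)."""
    series = read_binseries_table(path)
    if len(series) != 1:
        raise ParseError(
            f"expected a single animal, found {len(series)}: "
            f"{[s.animal_id for s in series]}")
    return series[0]
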