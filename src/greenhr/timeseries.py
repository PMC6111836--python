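"""Heart-rate time series: data model, CSV I/O, gap filling, hourly aggregation.

A smartband nominally reports one beats-per-minute (bpm) reading per minute,
but real streams have gaps (dirty sensor glass, loose fit).  This module
provides the flat data model every other stage consumes:

* :class:`HRSample` — one timestamped bpm reading,
* :class:`DaySeries` — one calendar day's ordered readings,
* :class:`HourlyAggregate` — per-hour mean/max/count, the unit all
  thresholding compares against.

CSV dialect is fixed: header ``timestamp,bpm``, ISO-8601 timestamps, UTF-8.
Timestamps are treated as local wall-clock time, since daily routines
(sleep, exercise) are defined in local terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParseError, ValidationError

__all__ = [
    "HRSample",
    "DaySeries",
    "HourlyAggregate",
    "InterpolationResult",
    "read_samples",
    "write_samples",
    "interpolate_missing",
    "hourly_aggregate",
    "aggregates_to_tsv",
    "day_extrema",
]

#: sanity bounds for a heart-rate reading; outside means a corrupt row
BPM_MIN, BPM_MAX = 0.0, 300.0


@dataclass(frozen=True, order=True)
class HRSample:
    """One heart-rate reading: instant ``t`` and beats per minute ``bpm``."""

    t: datetime
    bpm: float

    def __post_init__(self) -> None:
        if not (BPM_MIN < self.bpm < BPM_MAX):
            raise ValidationError(
                f"bpm {self.bpm!r} outside ({BPM_MIN}, {BPM_MAX}) at {self.t}"
            )


@dataclass(frozen=True)
class DaySeries:
    """An ordered heart-rate trace for a single calendar day.

    Samples must be strictly increasing in time and all fall on ``date``.
    ``weekday`` follows the ISO convention used throughout: Monday = 0.
    """

    date: date
    samples: tuple[HRSample, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.samples, self.samples[1:]):
            if a.t >= b.t:
                raise ValidationError(
                    f"samples not strictly increasing: {a.t} then {b.t}"
                )
        for s in self.samples:
            if s.t.date() != self.date:
                raise ValidationError(
                    f"sample at {s.t} does not fall on {self.date}"
                )

    @property
    def weekday(self) -> int:
        return self.date.weekday()

    @property
    def bpm(self) -> np.ndarray:
        return np.array([s.bpm for s in self.samples], dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class HourlyAggregate:
    """Summary of one hour bucket ``[hour, hour+1)`` of a day.

    Hours with no samples have no aggregate at all — absence is never
    represented as zero bpm.
    """

    hour: int
    mean_bpm: float
    max_bpm: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.hour <= 23:
            raise ValidationError(f"hour {self.hour} outside 0-23")
        if self.n < 1:
            raise ValidationError("an HourlyAggregate needs >= 1 sample")
        if self.mean_bpm > self.max_bpm + 1e-9:
            raise ValidationError("mean_bpm exceeds max_bpm")


@dataclass(frozen=True)
class InterpolationResult:
    """A gap-filled day plus bookkeeping on how much was filled.

    ``missing_fraction`` mirrors the field convention of reporting the share
    of grid points that had to be estimated (e.g. "9.02% missing").
    """

    day: DaySeries
    n_filled: int
    n_grid: int

    @property
    def missing_fraction(self) -> float:
        return self.n_filled / self.n_grid


def read_samples(path: str | Path) -> list[DaySeries]:
    """Read a ``timestamp,bpm`` CSV into per-day series.

    Rows are grouped by calendar date; out-of-order rows are sorted;
    duplicate timestamps are an error (the device emits at most one reading
    per minute).  Malformed rows raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"bpm": float})
    except FileNotFoundError:
        raise
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != ["timestamp", "bpm"]:
        raise ParseError(
            f"{path}: expected header 'timestamp,bpm', got {list(df.columns)}"
        )
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce")
    bad = ts.isna() | df["bpm"].isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
        raise ParseError(f"{path}: malformed row at line {line}")
    samples = sorted(
        HRSample(t.to_pydatetime(), float(b)) for t, b in zip(ts, df["bpm"])
    )
    for a, b in zip(samples, samples[1:]):
        if a.t == b.t:
            raise ValidationError(f"{path}: duplicate timestamp {a.t}")
    days: dict[date, list[HRSample]] = {}
    for s in samples:
        days.setdefault(s.t.date(), []).append(s)
    return [DaySeries(d, tuple(ss)) for d, ss in sorted(days.items())]


def write_samples(days: Iterable[DaySeries], path: str | Path) -> None:
    """Write day series back out in the same ``timestamp,bpm`` dialect."""
    rows = [
        {"timestamp": s.t.isoformat(), "bpm": s.bpm}
        for day in days
        for s in day.samples
    ]
    pd.DataFrame(rows, columns=["timestamp", "bpm"]).to_csv(path, index=False)


def interpolate_missing(
    day: DaySeries, step: timedelta = timedelta(minutes=1)
) -> InterpolationResult:
    """Fill gaps in a day by linear interpolation on a regular grid.

    The grid runs from the first to the last sample at ``step`` spacing;
    existing on-grid samples are preserved exactly and values are never
    extrapolated beyond the endpoints.  Gaps across midnight are never
    filled because days are analysed independently.
    """
    if len(day) < 2:
        raise InsufficientDataError(
            f"need >= 2 samples to interpolate, got {len(day)}"
        )
    t0 = day.samples[0].t
    step_s = step.total_seconds()
    xp = np.array([(s.t - t0).total_seconds() for s in day.samples])
    fp = day.bpm
    n_grid = int(xp[-1] // step_s) + 1
    grid = np.arange(n_grid) * step_s
    interp = np.interp(grid, xp, fp)
    # snap grid points that coincide with real samples back to exact values
    on_grid = np.isin(xp, grid)
    filled = n_grid - int(on_grid.sum())
    samples = tuple(
        HRSample(t0 + timedelta(seconds=float(g)), float(v))
        for g, v in zip(grid, interp)
    )
    return InterpolationResult(DaySeries(day.date, samples), filled, n_grid)


def hourly_aggregate(day: DaySeries) -> list[HourlyAggregate]:
    """Per-hour mean/max/count for every hour with at least one sample."""
    if not day.samples:
        return []
    df = pd.DataFrame(
        {"hour": [s.t.hour for s in day.samples], "bpm": day.bpm}
    )
    g = df.groupby("hour")["bpm"].agg(["mean", "max", "count"])
    return [
        HourlyAggregate(int(h), float(r["mean"]), float(r["max"]), int(r["count"]))
        for h, r in g.iterrows()
    ]


def aggregates_to_tsv(
    date_: date, aggs: Sequence[HourlyAggregate], path: str | Path
) -> None:
    """Export hourly aggregates as ``date, hour, mean_bpm, max_bpm, n`` TSV."""
    pd.DataFrame(
        [
            {
                "date": date_.isoformat(),
                "hour": a.hour,
                "mean_bpm": round(a.mean_bpm, 2),
                "max_bpm": round(a.max_bpm, 2),
                "n": a.n,
            }
            for a in aggs
        ],
        columns=["date", "hour", "mean_bpm", "max_bpm", "n"],
    ).to_csv(path, sep="\t", index=False)


def day_extrema(day: DaySeries) -> tuple[float, float]:
    """Return ``(r_max, r_min)``, the day's extreme heart rates.

    These are the two inputs of the daily risk threshold.
    """
    if not day.samples:
        raise InsufficientDataError("day has no samples")
    bpm = day.bpm
    return float(bpm.max()), float(bpm.min())
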