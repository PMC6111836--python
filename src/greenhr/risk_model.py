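"""Two-stage risk-interval model for routine heart-rate monitoring.

Stage one operates per day: the daily threshold is the weighted average

    t = (2/3) * Rmax + (1/3) * Rmin

of the day's extreme heart rates, weighted towards the maximum so that only
genuinely elevated hours are flagged; every hour whose *mean* bpm strictly
exceeds t becomes a risky hourly range.

Stage two operates per 3-week training slot: the training threshold

    Tt = mean(weekly maxima) * ratio        (ratio defaults to 0.8)

filters the per-day risky ranges, and the prediction for the coming week is
the union over the three weeks of the surviving ranges, keyed by
(weekday, hour).  The slot slides weekly, so routine changes age out of the
prediction after three weeks.

All threshold comparisons are strict (>): an hour exactly at a threshold is
not risky.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ValidationError
from .timeseries import DaySeries, day_extrema, hourly_aggregate

__all__ = [
    "RiskyRange",
    "WeeklyProfile",
    "TrainingThreshold",
    "Prediction",
    "daily_threshold",
    "detect_risky_ranges",
    "training_threshold",
    "select_prediction_ranges",
    "build_prediction",
    "recalculate_routines",
    "week_table",
    "prediction_table",
]

#: default ratio applied to the mean of the weekly maxima
DEFAULT_RATIO = 0.8

#: length of the sliding training slot, in weeks
TRAINING_WEEKS = 3


def daily_threshold(r_max: float, r_min: float) -> float:
    """Weighted-average daily threshold ``(2/3)*r_max + (1/3)*r_min``.

    Always lies in ``[r_min, r_max]``.
    """
    if r_max < r_min:
        raise ValidationError(f"r_max {r_max} < r_min {r_min}")
    if r_min <= 0:
        raise ValidationError(f"r_min must be positive, got {r_min}")
    return (2.0 / 3.0) * r_max + r_min / 3.0


@dataclass(frozen=True)
class RiskyRange:
    """One hour of one day whose mean bpm exceeded that day's threshold."""

    date: date
    hour: int
    mean_bpm: float

    @property
    def weekday(self) -> int:
        return self.date.weekday()


@dataclass(frozen=True)
class TrainingThreshold:
    """The bar a risky range must clear to enter the prediction.

    ``tt = mean(week_maxima) * ratio``; with ratio <= 1 it never exceeds
    the largest weekly maximum.
    """

    tt: float
    ratio: float
    week_maxima: tuple[float, ...]


def training_threshold(
    week_maxima: Sequence[float], ratio: float = DEFAULT_RATIO
) -> TrainingThreshold:
    """Training threshold from one maximum bpm per training week."""
    if not week_maxima:
        raise ValidationError("need at least one weekly maximum")
    if not 0.0 < ratio <= 1.0:
        raise ValidationError(f"ratio must be in (0, 1], got {ratio}")
    maxima = tuple(float(m) for m in week_maxima)
    tt = ratio * sum(maxima) / len(maxima)
    return TrainingThreshold(tt=tt, ratio=ratio, week_maxima=maxima)


def detect_risky_ranges(day: DaySeries) -> list[RiskyRange]:
    """Hours of ``day`` whose mean bpm strictly exceeds the daily threshold."""
    t = daily_threshold(*day_extrema(day))
    return [
        RiskyRange(day.date, a.hour, a.mean_bpm)
        for a in hourly_aggregate(day)
        if a.mean_bpm > t
    ]


@dataclass(frozen=True)
class WeeklyProfile:
    """One Monday-to-Sunday week: its traces, maximum bpm and risky ranges.

    ``days`` holds one optional :class:`DaySeries` per weekday (a day with
    no data is ``None``).  ``week_max_bpm`` and ``risky_ranges`` may be
    supplied directly — e.g. when reconstructing a week from a published
    summary table — or derived from traces via :meth:`from_days`.
    """

    start_date: date
    days: tuple[Optional[DaySeries], ...]
    week_max_bpm: float
    risky_ranges: tuple[RiskyRange, ...]

    def __post_init__(self) -> None:
        if self.start_date.weekday() != 0:
            raise ValidationError(f"{self.start_date} is not a Monday")
        if len(self.days) != 7:
            raise ValidationError("a week holds exactly 7 (optional) days")
        end = self.start_date + timedelta(days=7)
        for r in self.risky_ranges:
            if not self.start_date <= r.date < end:
                raise ValidationError(
                    f"risky range on {r.date} outside week of {self.start_date}"
                )

    @classmethod
    def from_days(cls, days: Iterable[DaySeries]) -> "WeeklyProfile":
        """Derive a weekly profile from day traces of one calendar week."""
        day_list = [d for d in days if d is not None and len(d) > 0]
        if not day_list:
            raise ValidationError("a week needs at least one non-empty day")
        monday = day_list[0].date - timedelta(days=day_list[0].weekday)
        slots: list[Optional[DaySeries]] = [None] * 7
        for d in day_list:
            if d.date - timedelta(days=d.weekday) != monday:
                raise ValidationError(
                    f"{d.date} is not in the week starting {monday}"
                )
            slots[d.weekday] = d
        week_max = max(day_extrema(d)[0] for d in day_list)
        ranges = tuple(
            r for d in day_list for r in detect_risky_ranges(d)
        )
        return cls(monday, tuple(slots), week_max, ranges)


def select_prediction_ranges(
    ranges: Iterable[RiskyRange], tt: TrainingThreshold
) -> list[RiskyRange]:
    """Risky ranges whose mean bpm strictly exceeds the training threshold."""
    return [r for r in ranges if r.mean_bpm > tt.tt]


@dataclass(frozen=True)
class Prediction:
    """The (weekday, hour) slots to sample at high frequency next week."""

    slots: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for wd, h in self.slots:
            if not (0 <= wd <= 6 and 0 <= h <= 23):
                raise ValidationError(f"slot ({wd}, {h}) outside week grid")

    def to_json(self) -> str:
        return json.dumps(
            {"slots": sorted([wd, h] for wd, h in self.slots)}, indent=0
        )

    @classmethod
    def from_json(cls, text: str) -> "Prediction":
        data = json.loads(text)
        return cls(frozenset((int(wd), int(h)) for wd, h in data["slots"]))

    @classmethod
    def load(cls, path: str | Path) -> "Prediction":
        return cls.from_json(Path(path).read_text())

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def build_prediction(
    weeks: Sequence[WeeklyProfile], ratio: float = DEFAULT_RATIO
) -> Prediction:
    """Prediction for the coming week from a 3-week training slot.

    The training threshold is computed from the three weekly maxima; each
    week's risky ranges are filtered by it; the prediction is the union of
    the surviving ranges across weeks, keyed by (weekday, hour).  Union —
    not intersection — so a routine present in only one training week is
    still monitored.
    """
    if len(weeks) != TRAINING_WEEKS:
        raise ValidationError(
            f"training slot is {TRAINING_WEEKS} weeks, got {len(weeks)}"
        )
    tt = training_threshold([w.week_max_bpm for w in weeks], ratio)
    slots = {
        (r.weekday, r.hour)
        for w in weeks
        for r in select_prediction_ranges(w.risky_ranges, tt)
    }
    return Prediction(frozenset(slots))


def recalculate_routines(
    history: Sequence[WeeklyProfile],
    previous: Prediction,
    ratio: float = DEFAULT_RATIO,
) -> Prediction:
    """Weekly mark-and-sweep update of the prediction.

    Slots confirmed by the latest 3-week window are marked (re-added);
    previously predicted slots that the window no longer supports are swept
    away.  The result therefore equals :func:`build_prediction` on the
    window — the ``previous`` argument documents which slots were dropped
    rather than influencing the outcome.
    """
    fresh = build_prediction(history, ratio)
    marked = (previous.slots & fresh.slots) | (fresh.slots - previous.slots)
    return Prediction(frozenset(marked))


_WEEKDAYS = [
    "Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday",
    "Sunday",
]


def week_table(week: WeeklyProfile, tt: TrainingThreshold) -> pd.DataFrame:
    """Per-week summary table: one row per day with threshold and ranges.

    Mirrors the conventional report shape ``day, max_pulsation, threshold,
    ranges, date, ranges_above_tt``; bpm values are rounded to 2 decimals
    for display only.
    """
    rows = []
    by_day: dict[date, list[RiskyRange]] = {}
    for r in week.risky_ranges:
        by_day.setdefault(r.date, []).append(r)
    for wd in range(7):
        d = week.start_date + timedelta(days=wd)
        day = week.days[wd]
        if day is not None and len(day) > 0:
            r_max, r_min = day_extrema(day)
            thr = f"{daily_threshold(r_max, r_min):.2f}"
            max_p = f"{r_max:.2f}"
        else:
            thr = max_p = "-"
        ranges = sorted(by_day.get(d, []), key=lambda r: r.hour)
        rows.append(
            {
                "day": _WEEKDAYS[wd],
                "max_pulsation": max_p,
                "threshold": thr,
                "ranges": ";".join(
                    f"{r.hour}-{(r.hour + 1) % 24}:{r.mean_bpm:.2f}"
                    for r in ranges
                ) or "-",
                "date": d.isoformat(),
                "ranges_above_tt": ";".join(
                    f"{r.hour}-{(r.hour + 1) % 24}"
                    for r in ranges
                    if r.mean_bpm > tt.tt
                ) or "-",
            }
        )
    return pd.DataFrame(rows)


def prediction_table(prediction: Prediction) -> pd.DataFrame:
    """Prediction as a ``weekday, hour`` table sorted by slot."""
    rows = [
        {"weekday": _WEEKDAYS[wd], "hour": h}
        for wd, h in sorted(prediction.slots)
    ]
    return pd.DataFrame(rows, columns=["weekday", "hour"])
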