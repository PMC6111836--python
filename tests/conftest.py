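"""Shared fixtures: hand-built day traces, published weekly summaries, and
an independent brute-force re-derivation of the prediction pipeline."""

from __future__ import annotations

from datetime import date, datetime, timedelta

import pytest

from greenhr.risk_model import RiskyRange, WeeklyProfile
from greenhr.timeseries import DaySeries, HRSample


def make_day(day_date: date, hourly: dict[int, list[float]]) -> DaySeries:
    """Build a day trace placing each hour's bpm values at minutes 0, 1, ..."""
    samples = []
    midnight = datetime.combine(day_date, datetime.min.time())
    for hour in sorted(hourly):
        for minute, bpm in enumerate(hourly[hour]):
            samples.append(
                HRSample(midnight + timedelta(hours=hour, minutes=minute), bpm)
            )
    return DaySeries(day_date, tuple(samples))


def table_week(
    start_iso: str, week_max: float, ranges: dict[int, list[tuple[int, float]]]
) -> WeeklyProfile:
    """Weekly profile reconstructed from a published summary table.

    ``ranges`` maps day offset within the week (0 = Monday) to
    ``(hour, mean_bpm)`` pairs; the raw traces are unavailable, so ``days``
    is empty and the summary quantities are supplied directly.
    """
    start = date.fromisoformat(start_iso)
    risky = tuple(
        RiskyRange(start + timedelta(days=off), hour, mean)
        for off, pairs in ranges.items()
        for hour, mean in pairs
    )
    return WeeklyProfile(start, (None,) * 7, week_max, risky)


@pytest.fixture(scope="session")
def week1() -> WeeklyProfile:
    """Training week of 16-22 April: Thursday swim, Saturday night out."""
    return table_week(
        "2018-04-16",
        134.0,
        {
            1: [(17, 92.50), (18, 84.00), (19, 84.40)],
            3: [(21, 118.36)],
            4: [(20, 92.80), (23, 96.00)],
            5: [(0, 106.00), (1, 99.64), (2, 110.60)],
            6: [(16, 102.00), (17, 107.64), (20, 100.00)],
        },
    )


@pytest.fixture(scope="session")
def week2() -> WeeklyProfile:
    """Training week of 30 April - 6 May."""
    return table_week(
        "2018-04-30",
        123.0,
        {
            2: [(18, 90.0), (19, 81.64), (20, 81.16), (21, 83.64), (22, 80.86)],
            3: [(21, 107.36), (22, 104.00)],
            4: [(19, 99.25), (21, 99.64), (22, 103.60), (23, 98.00)],
            5: [(0, 103.50), (1, 102.36)],
            6: [(0, 86.50), (2, 84.20)],
        },
    )


@pytest.fixture(scope="session")
def week3() -> WeeklyProfile:
    """Training week of 7-13 May."""
    return table_week(
        "2018-05-07",
        134.0,
        {
            0: [(16, 78.64), (21, 79.20)],
            1: [(22, 88.40)],
            3: [(21, 114.40)],
            4: [(18, 89.36), (19, 95.80), (20, 93.25), (23, 89.36)],
            5: [(23, 85.00)],
            6: [(0, 83.00), (1, 77.50), (14, 78.86), (15, 76.00)],
        },
    )


@pytest.fixture(scope="session")
def week6() -> WeeklyProfile:
    """Training week of 4-10 June (second validation case)."""
    return table_week(
        "2018-06-04",
        112.0,
        {
            1: [(16, 83.40), (17, 83.50), (18, 81.50)],
            2: [(16, 77.20), (17, 82.00)],
            4: [(20, 92.25), (22, 92.50)],
            5: [(14, 92.0)],
            6: [(16, 85.75)],
        },
    )


def brute_force_prediction(
    weeks: list[WeeklyProfile], ratio: float = 0.8
) -> set[tuple[int, int]]:
    """Re-derive the prediction from raw traces with plain-Python loops.

    Independent of the library code path (no pandas, no shared helpers):
    every hourly mean, every extremum and every comparison is recomputed
    from the samples alone.
    """
    maxima = []
    per_week_ranges: list[list[tuple[int, int, float]]] = []
    for week in weeks:
        wmax = float("-inf")
        ranges: list[tuple[int, int, float]] = []
        for day in week.days:
            if day is None or not day.samples:
                continue
            vals = [s.bpm for s in day.samples]
            wmax = max(wmax, max(vals))
            t = 2.0 * max(vals) / 3.0 + min(vals) / 3.0
            by_hour: dict[int, list[float]] = {}
            for s in day.samples:
                by_hour.setdefault(s.t.hour, []).append(s.bpm)
            for h, v in by_hour.items():
                m = sum(v) / len(v)
                if m > t:
                    ranges.append((day.date.weekday(), h, m))
        maxima.append(wmax)
        per_week_ranges.append(ranges)
    tt = ratio * sum(maxima) / len(maxima)
    return {
        (wd, h)
        for ranges in per_week_ranges
        for wd, h, m in ranges
        if m > tt
    }
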