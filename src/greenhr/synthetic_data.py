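"""Synthetic heart-rate streams with a daily-routine structure.

The generator emulates the minute-level traces of a wearer with a regular
routine: sleep at 60-70 bpm, waking hours inside a 60-100 bpm band, and
scheduled exercise bouts that ramp up to a 100-134 bpm peak and then decay
slowly afterwards.  Independent Gaussian noise is added per minute and a
configurable fraction of samples is deleted uniformly at random, mimicking
sensor dropouts.  Everything is deterministic under a fixed seed, with the
per-day stream keyed by (seed, calendar date) so any day can be regenerated
in isolation.

Only minute-level means are modelled — no beat-to-beat variability — which
is all the hourly-mean thresholding pipeline can see.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Optional

import numpy as np

from .errors import ValidationError
from .risk_model import WeeklyProfile
from .timeseries import DaySeries, HRSample

__all__ = [
    "ExerciseSlot",
    "RoutineProfile",
    "generate_day",
    "generate_weeks",
]

#: physiological clamp applied after noise
CLIP_LO, CLIP_HI = 40.0, 200.0

#: minutes to ramp up to the exercise peak, and to decay back afterwards
RAMP_MINUTES = 10
DECAY_MINUTES = 30


@dataclass(frozen=True)
class ExerciseSlot:
    """A recurring bout: weekday, hour interval [start, end), peak bpm."""

    weekday: int
    start_hour: int
    end_hour: int
    peak_bpm: float = 120.0

    def __post_init__(self) -> None:
        if not 0 <= self.weekday <= 6:
            raise ValidationError(f"weekday {self.weekday} outside 0-6")
        if not 0 <= self.start_hour < self.end_hour <= 24:
            raise ValidationError(
                f"bout hours [{self.start_hour}, {self.end_hour}) invalid"
            )

    @property
    def slots(self) -> frozenset[tuple[int, int]]:
        """The (weekday, hour) cells this bout occupies."""
        return frozenset(
            (self.weekday, h) for h in range(self.start_hour, self.end_hour)
        )


@dataclass(frozen=True)
class RoutineProfile:
    """Parameters of a wearer's weekly routine.

    ``day_bpm_range`` is the waking band; the generated waking baseline sits
    at its midpoint.  ``peak_bpm`` of every bout must exceed the band's top,
    otherwise exercise would be indistinguishable from ordinary activity.
    """

    sleep_window: tuple[int, int] = (0, 8)
    sleep_bpm: float = 65.0
    day_bpm_range: tuple[float, float] = (60.0, 100.0)
    exercise_slots: tuple[ExerciseSlot, ...] = (
        ExerciseSlot(weekday=3, start_hour=21, end_hour=22, peak_bpm=120.0),
    )
    noise_sd: float = 3.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        s, e = self.sleep_window
        if not 0 <= s < e <= 24:
            raise ValidationError(f"sleep window [{s}, {e}) invalid")
        if not 0.0 <= self.missing_rate < 0.2:
            raise ValidationError(
                f"missing_rate {self.missing_rate} outside [0, 0.2)"
            )
        lo, hi = self.day_bpm_range
        if not 0 < lo < hi:
            raise ValidationError(f"day bpm range ({lo}, {hi}) invalid")
        for slot in self.exercise_slots:
            if slot.peak_bpm <= hi:
                raise ValidationError(
                    f"bout peak {slot.peak_bpm} must exceed waking band top {hi}"
                )

    @property
    def waking_bpm(self) -> float:
        lo, hi = self.day_bpm_range
        return (lo + hi) / 2.0

    @property
    def expected_slots(self) -> frozenset[tuple[int, int]]:
        """All (weekday, hour) cells covered by the profile's bouts."""
        return frozenset(s for b in self.exercise_slots for s in b.slots)


def _minute_means(profile: RoutineProfile, weekday: int) -> np.ndarray:
    """Noise-free minute-by-minute mean bpm for one day of the routine."""
    means = np.full(1440, profile.waking_bpm)
    s, e = profile.sleep_window
    means[s * 60 : e * 60] = profile.sleep_bpm
    for bout in profile.exercise_slots:
        if bout.weekday != weekday:
            continue
        start, end = bout.start_hour * 60, bout.end_hour * 60
        base = float(means[start - 1]) if start > 0 else profile.waking_bpm
        ramp = min(RAMP_MINUTES, end - start)
        means[start : start + ramp] = np.linspace(
            base, bout.peak_bpm, ramp, endpoint=False
        )
        means[start + ramp : end] = bout.peak_bpm
        # slow return to baseline after the bout
        decay_end = min(end + DECAY_MINUTES, 1440)
        n_decay = decay_end - end
        if n_decay > 0:
            after = float(means[decay_end]) if decay_end < 1440 else profile.waking_bpm
            means[end:decay_end] = np.linspace(
                bout.peak_bpm, after, n_decay, endpoint=False
            )
    return means


def generate_day(profile: RoutineProfile, day_date: date) -> DaySeries:
    """One day's minute-level trace under the profile's routine.

    The random stream is keyed by ``(profile.seed, day_date)``, so the same
    profile always yields the identical trace for the same date.
    """
    rng = np.random.default_rng([profile.seed, day_date.toordinal()])
    bpm = _minute_means(profile, day_date.weekday())
    if profile.noise_sd > 0:
        bpm = bpm + rng.normal(0.0, profile.noise_sd, size=1440)
        bpm = np.clip(bpm, CLIP_LO, CLIP_HI)
    keep = np.ones(1440, dtype=bool)
    if profile.missing_rate > 0:
        keep = rng.random(1440) >= profile.missing_rate
        if keep.sum() < 2:  # pathological draw; keep the endpoints
            keep[[0, -1]] = True
    midnight = datetime.combine(day_date, datetime.min.time())
    samples = tuple(
        HRSample(midnight + timedelta(minutes=int(m)), float(bpm[m]))
        for m in np.nonzero(keep)[0]
    )
    return DaySeries(day_date, samples)


def generate_weeks(
    profile: RoutineProfile,
    n_weeks: int,
    start: date = date(2018, 4, 16),
    change_at: Optional[int] = None,
    new_profile: Optional[RoutineProfile] = None,
) -> list[WeeklyProfile]:
    """Consecutive Monday-to-Sunday weeks of the routine.

    From week index ``change_at`` (0-based) onward the wearer switches to
    ``new_profile`` — the scenario the sliding-window recalculation must
    adapt to.  ``start`` must be a Monday.
    """
    if n_weeks < 1:
        raise ValidationError(f"n_weeks must be >= 1, got {n_weeks}")
    if start.weekday() != 0:
        raise ValidationError(f"start {start} is not a Monday")
    if (change_at is None) != (new_profile is None):
        raise ValidationError("change_at and new_profile go together")
    weeks = []
    for w in range(n_weeks):
        p = profile if change_at is None or w < change_at else new_profile
        days = [
            generate_day(p, start + timedelta(days=7 * w + wd))
            for wd in range(7)
        ]
        weeks.append(WeeklyProfile.from_days(days))
    return weeks
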