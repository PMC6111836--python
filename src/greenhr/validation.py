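"""Day-level train/validate procedure and cohort summary statistics.

When only a few consecutive days are available per subject, the weekly
pipeline is collapsed to day scale: one day trains, the next validates.
Training marks every hour whose *maximum* bpm strictly exceeds the day's
weighted-average threshold (note the contrast with the weekly model, which
compares hourly *means*).  Validation re-derives the risk set on the second
day and scores agreement hour by hour: a match is an hour whose risk status
— risky or not — is the same on both days, and the denominator is the hours
observed on both days, so accuracy adapts to data availability.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, stdev
from typing import Sequence

from .errors import InsufficientDataError, ValidationError
from .risk_model import daily_threshold
from .timeseries import DaySeries, day_extrema, hourly_aggregate

__all__ = [
    "DayRiskSet",
    "AccuracyResult",
    "day_train",
    "day_validate",
    "cohort_summary",
]


@dataclass(frozen=True)
class DayRiskSet:
    """Hours of one day marked risky, plus the hours that had any data."""

    hours: frozenset[int]
    observed_hours: frozenset[int]

    def __post_init__(self) -> None:
        if not self.hours <= self.observed_hours:
            raise ValidationError("risk hours must be observed hours")


@dataclass(frozen=True)
class AccuracyResult:
    """Hour-by-hour agreement between a trained and a validation day."""

    matches: int
    comparable_hours: int

    def __post_init__(self) -> None:
        if not 0 <= self.matches <= self.comparable_hours:
            raise ValidationError(
                f"matches {self.matches} outside [0, {self.comparable_hours}]"
            )

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.matches / self.comparable_hours


def day_train(day: DaySeries) -> DayRiskSet:
    """Mark hours whose maximum bpm strictly exceeds the daily threshold."""
    t = daily_threshold(*day_extrema(day))
    aggs = hourly_aggregate(day)
    observed = frozenset(a.hour for a in aggs)
    risky = frozenset(a.hour for a in aggs if a.max_bpm > t)
    return DayRiskSet(risky, observed)


def day_validate(trained: DayRiskSet, validation_day: DaySeries) -> AccuracyResult:
    """Score the trained risk set against the next day's own risk set.

    Only hours observed on both days are comparable; agreement counts both
    risky-risky and nonrisky-nonrisky hours.
    """
    observed = day_train(validation_day)
    comparable = trained.observed_hours & observed.observed_hours
    if not comparable:
        raise InsufficientDataError(
            "no hour observed on both days; accuracy undefined"
        )
    matches = sum(
        1
        for h in comparable
        if (h in trained.hours) == (h in observed.hours)
    )
    return AccuracyResult(matches, len(comparable))


def cohort_summary(
    results: Sequence[AccuracyResult | float],
) -> tuple[float, float]:
    """Mean and sample standard deviation of per-user accuracies, in percent."""
    if len(results) < 2:
        raise ValidationError("cohort summary needs at least 2 results")
    vals = [
        r.accuracy_pct if isinstance(r, AccuracyResult) else float(r)
        for r in results
    ]
    return mean(vals), stdev(vals)
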