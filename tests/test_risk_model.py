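"""Two-stage thresholding: daily threshold, risky ranges, training
threshold, 3-week union prediction, weekly recalculation."""

import itertools
from datetime import date

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greenhr.errors import ValidationError
from greenhr.risk_model import (
    Prediction,
    RiskyRange,
    WeeklyProfile,
    build_prediction,
    daily_threshold,
    detect_risky_ranges,
    prediction_table,
    recalculate_routines,
    select_prediction_ranges,
    training_threshold,
    week_table,
)
from greenhr.synthetic_data import ExerciseSlot, RoutineProfile, generate_weeks

from conftest import brute_force_prediction, make_day


class TestDailyThreshold:
    def test_weighted_average_by_hand(self):
        assert daily_threshold(120, 60) == pytest.approx(100.0)
        # the 93/49 bpm quiet day: (2/3)*93 + 49/3 = 78.33
        assert daily_threshold(93, 49) == pytest.approx(78.3333, abs=1e-3)

    @given(x=st.floats(40, 200))
    @settings(max_examples=30, derandomize=True)
    def test_degenerate_extrema_return_themselves(self, x):
        assert daily_threshold(x, x) == pytest.approx(x)

    @given(
        r_min=st.floats(30, 150),
        spread=st.floats(0, 100),
    )
    @settings(max_examples=50, derandomize=True)
    def test_threshold_lies_between_extrema(self, r_min, spread):
        r_max = r_min + spread
        t = daily_threshold(r_max, r_min)
        assert r_min - 1e-9 <= t <= r_max + 1e-9

    def test_swapped_extrema_rejected(self):
        with pytest.raises(ValidationError):
            daily_threshold(60, 120)


class TestDetectRiskyRanges:
    def test_constant_day_has_no_risky_hours(self):
        day = make_day(date(2018, 5, 7), {h: [70.0, 70.0] for h in range(24)})
        assert detect_risky_ranges(day) == []

    def test_swim_evening_flagged_with_printed_numbers(self):
        # reconstruct a day whose extrema give t = 106.67 and whose
        # hour-21 mean is 118.36 -- the flagged Thursday swim session
        day = make_day(
            date(2018, 4, 19),
            {
                0: [52.01, 60.0],
                12: [80.0] * 10,
                21: [134.0, 102.72],  # mean 118.36, attains the day max
            },
        )
        t = daily_threshold(134.0, 52.01)
        assert t == pytest.approx(106.67, abs=0.01)
        ranges = detect_risky_ranges(day)
        assert [(r.hour, round(r.mean_bpm, 2)) for r in ranges] == [(21, 118.36)]

    def test_agrees_with_exhaustive_comparison(self):
        """Every hourly mean compared to an independently computed t."""
        day = make_day(
            date(2018, 5, 10),
            {h: [60 + 3 * h + (m % 5) for m in range(12)] for h in range(24)},
        )
        vals = [s.bpm for s in day.samples]
        t = 2 * max(vals) / 3 + min(vals) / 3
        expected = set()
        for h in range(24):
            hv = [s.bpm for s in day.samples if s.t.hour == h]
            if sum(hv) / len(hv) > t:
                expected.add(h)
        assert {r.hour for r in detect_risky_ranges(day)} == expected


class TestTrainingThreshold:
    @pytest.mark.parametrize(
        "maxima, expected",
        [
            ((134, 123, 134), 104.27),  # mean 130.33, ratio 0.8
            ((134, 123, 112), 98.40),   # mean 123.00, ratio 0.8
        ],
    )
    def test_published_parameterisations(self, maxima, expected):
        tt = training_threshold(maxima, 0.8)
        assert round(tt.tt, 2) == expected

    def test_identity_ratio_single_week(self):
        assert training_threshold([100], 1.0).tt == 100

    def test_never_exceeds_largest_weekly_maximum(self):
        tt = training_threshold([134, 123, 112], 0.99)
        assert tt.tt <= max(tt.week_maxima)

    def test_empty_maxima_rejected(self):
        with pytest.raises(ValidationError):
            training_threshold([])

    @pytest.mark.parametrize("ratio", [0.0, -0.1, 1.2])
    def test_ratio_outside_unit_interval_rejected(self, ratio):
        with pytest.raises(ValidationError):
            training_threshold([120], ratio)


class TestSelectPredictionRanges:
    def test_saturday_night_ranges_vs_tt(self, week1):
        """Of Saturday's 0-1 (106.00), 1-2 (99.64), 2-3 (110.60), only the
        two above tt=104.27 survive."""
        tt = training_threshold([134, 123, 134], 0.8)
        saturday = [r for r in week1.risky_ranges if r.weekday == 5]
        kept = select_prediction_ranges(saturday, tt)
        assert {(r.hour) for r in kept} == {0, 2}

    def test_strict_comparison_excludes_borderline_hour(self, week2):
        """Thursday 22-23 at 104.00 sits below tt=104.27 and is dropped;
        only 21-22 (107.36) survives from the whole week."""
        tt = training_threshold([134, 123, 134], 0.8)
        kept = select_prediction_ranges(week2.risky_ranges, tt)
        assert [(r.weekday, r.hour) for r in kept] == [(3, 21)]

    def test_empty_input_empty_output(self):
        tt = training_threshold([120])
        assert select_prediction_ranges([], tt) == []


class TestBuildPrediction:
    def test_published_three_week_case(self, week1, week2, week3):
        pred = build_prediction([week1, week2, week3])
        assert pred.slots == {(3, 21), (5, 0), (5, 2), (6, 17)}

    def test_second_validation_case_strict_rule(self, week1, week2, week6):
        """With tt=98.40 the union holds 11 slots; Friday 23-0 (mean 98.00)
        fails the strict comparison and stays out."""
        pred = build_prediction([week1, week2, week6])
        assert (4, 23) not in pred.slots
        assert len(pred.slots) == 11
        assert {(3, 21), (3, 22), (4, 19), (5, 1), (6, 16)} <= pred.slots

    def test_order_invariance(self, week1, week2, week3):
        preds = {
            build_prediction(list(p)).slots
            for p in itertools.permutations([week1, week2, week3])
        }
        assert len(preds) == 1

    def test_identical_weeks_equal_single_week_filter(self, week1):
        pred = build_prediction([week1, week1, week1])
        tt = training_threshold([week1.week_max_bpm] * 3)
        single = {
            (r.weekday, r.hour)
            for r in select_prediction_ranges(week1.risky_ranges, tt)
        }
        assert pred.slots == single

    def test_no_surviving_ranges_gives_empty_prediction(self, week6):
        assert build_prediction([week6, week6, week6], ratio=1.0).slots == set()

    def test_wrong_week_count_rejected(self, week1, week2):
        with pytest.raises(ValidationError):
            build_prediction([week1, week2])

    @pytest.mark.parametrize("lo, hi", [(0.5, 0.8), (0.8, 0.95), (0.7, 1.0)])
    def test_raising_ratio_never_adds_slots(self, week1, week2, week3, lo, hi):
        weeks = [week1, week2, week3]
        assert build_prediction(weeks, hi).slots <= build_prediction(weeks, lo).slots

    def test_prediction_subset_of_weekly_risky_ranges(self, week1, week2, week3):
        weeks = [week1, week2, week3]
        all_ranges = {
            (r.weekday, r.hour) for w in weeks for r in w.risky_ranges
        }
        assert build_prediction(weeks).slots <= all_ranges

    def test_agrees_with_brute_force_on_synthetic_traces(self):
        profile = RoutineProfile(
            exercise_slots=(
                ExerciseSlot(3, 21, 22, 125.0),
                ExerciseSlot(5, 7, 9, 115.0),
            ),
            noise_sd=4.0,
            missing_rate=0.05,
            seed=42,
        )
        weeks = generate_weeks(profile, 3)
        assert build_prediction(weeks).slots == brute_force_prediction(weeks)


class TestRecalculateRoutines:
    def test_unchanged_history_is_fixed_point(self, week1, week2, week3):
        history = [week1, week2, week3]
        previous = build_prediction(history)
        assert recalculate_routines(history, previous) == previous

    def test_abandoned_routine_slot_removed(self):
        """Three weeks without the Thursday 21-22 peak sweep that slot away."""
        active = RoutineProfile(seed=7, noise_sd=0.0)
        moved = RoutineProfile(
            seed=7,
            noise_sd=0.0,
            exercise_slots=(ExerciseSlot(5, 10, 11, 126.0),),
        )
        weeks = generate_weeks(moved, 3, start=date(2018, 5, 14))
        previous = build_prediction(generate_weeks(active, 3))
        assert (3, 21) in previous.slots
        updated = recalculate_routines(weeks, previous)
        assert (3, 21) not in updated.slots
        assert (5, 10) in updated.slots

    def test_new_routine_slot_added(self):
        """Three weeks of a new Tuesday 18-19 bout at 120 bpm mark the slot."""
        old = RoutineProfile(seed=9, noise_sd=0.0)
        new = RoutineProfile(
            seed=9,
            noise_sd=0.0,
            exercise_slots=(ExerciseSlot(1, 18, 19, 120.0),),
        )
        previous = build_prediction(generate_weeks(old, 3))
        assert (1, 18) not in previous.slots
        updated = recalculate_routines(
            generate_weeks(new, 3, start=date(2018, 5, 14)), previous
        )
        assert (1, 18) in updated.slots
        assert (3, 21) not in updated.slots

    def test_equals_build_prediction_always(self, week1, week2, week6):
        history = [week1, week2, week6]
        arbitrary = Prediction(frozenset({(0, 0), (6, 23)}))
        assert recalculate_routines(history, arbitrary) == build_prediction(history)


class TestExports:
    def test_week_table_shape_and_rounding(self, week1):
        tt = training_threshold([134, 123, 134])
        table = week_table(week1, tt)
        assert list(table.columns) == [
            "day", "max_pulsation", "threshold", "ranges", "date",
            "ranges_above_tt",
        ]
        thursday = table[table["day"] == "Thursday"].iloc[0]
        assert thursday["ranges"] == "21-22:118.36"
        assert thursday["ranges_above_tt"] == "21-22"

    def test_prediction_json_round_trip(self, week1, week2, week3):
        pred = build_prediction([week1, week2, week3])
        assert Prediction.from_json(pred.to_json()) == pred

    def test_prediction_table_sorted(self):
        table = prediction_table(Prediction(frozenset({(6, 17), (3, 21)})))
        assert table["hour"].tolist() == [21, 17]
        assert table["weekday"].tolist() == ["Thursday", "Sunday"]
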