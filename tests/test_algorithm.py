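"""The two-step selection algorithm and six-way categorization."""
from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from shiftlink import (
    Category,
    NurseShiftStat,
    SelectionMode,
    assign_all,
    compute_stats,
    step1_select,
    step2_select,
)
from conftest import events_frame, stays_frame
from _oracles import brute_force_assign, random_small_fixture

D = dt.datetime


def stat(nurse, count, interval_h=0.0, start=D(2019, 1, 1, 8)):
    last = start + dt.timedelta(hours=interval_h)
    if count == 1:
        last = start
    return NurseShiftStat(nurse, count, start, last)


class TestComputeStats:
    def test_counts_and_interval_from_unique_times(self):
        stats = compute_stats({
            "A": [D(2019, 1, 1, 8), D(2019, 1, 1, 9), D(2019, 1, 1, 17)],
            "B": [D(2019, 1, 1, 12)],
        })
        by = {s.nurse_id: s for s in stats}
        assert by["A"].chart_count == 3
        assert by["A"].interval == dt.timedelta(hours=9)
        assert by["B"].chart_count == 1
        assert by["B"].interval == dt.timedelta(0)

    def test_empty_mapping_gives_empty_stats(self):
        assert compute_stats({}) == []


class TestStep1Select:
    @pytest.mark.parametrize("stats,winner,mode", [
        ([stat("A", 12), stat("B", 3)], "A", SelectionMode.MAX_COUNT),
        ([stat("A", 5, 10), stat("B", 5, 2)], "A", SelectionMode.TIE_BROKEN),
        ([stat("A", 4, 6), stat("B", 4, 6)], None, SelectionMode.TIE_UNBROKEN),
        ([stat("A", 2, 1)], "A", SelectionMode.SOLE_CHARTER),
        ([], None, SelectionMode.NO_CHARTER),
    ])
    def test_selection_modes(self, stats, winner, mode):
        result = step1_select(stats)
        assert (result.nurse_id, result.mode) == (winner, mode)

    def test_order_invariance(self):
        stats = [stat("A", 5, 10), stat("B", 5, 2), stat("C", 3)]
        assert step1_select(stats) == step1_select(stats[::-1])

    def test_adding_events_for_winner_preserves_selection(self):
        # count strictly increases and interval never shrinks
        rng = np.random.default_rng(11)
        base = D(2019, 1, 1, 7)
        for _ in range(200):
            times = {
                f"N{i}": {
                    base + dt.timedelta(seconds=int(rng.integers(0, 43200)))
                    for _ in range(int(rng.integers(1, 8)))
                }
                for i in range(int(rng.integers(1, 5)))
            }
            winner = step1_select(compute_stats(times)).nurse_id
            if winner is None:
                continue
            extra = {base + dt.timedelta(seconds=int(rng.integers(0, 43200)))
                     for _ in range(int(rng.integers(1, 4)))}
            times[winner] = times[winner] | extra
            assert step1_select(compute_stats(times)).nurse_id == winner


class TestStep2AndCategories:
    def _run(self, shift_stats):
        """shift_stats: list of per-shift stat lists on consecutive windows."""
        shifts = []
        cursor = D(2019, 1, 1, 8)
        from shiftlink import shift_id_of
        first = shift_id_of(cursor)
        shifts = [first]
        for _ in shift_stats[1:]:
            shifts.append(shifts[-1].next())
        return step2_select(shifts, dict(zip(shifts, shift_stats)), "P1")

    def test_first_shift_has_no_exclusion(self):
        (a,) = self._run([[stat("A", 3, 2)]])
        assert a.primary_nurse_id == "A"
        assert a.category == Category.ONE_NURSE_CHARTED

    def test_sole_charter_equal_to_prior_primary_is_excluded(self):
        a1, a2 = self._run([[stat("A", 3, 2)], [stat("A", 5, 4)]])
        assert a1.primary_nurse_id == "A"
        assert a2.primary_nurse_id is None
        assert a2.category == Category.ONLY_PRIOR_PRIMARY_CHARTED
        assert a2.step1_nurse_id == "A"

    def test_exclusion_falls_back_to_next_best_charter(self):
        a1, a2 = self._run([
            [stat("A", 3, 2)],
            [stat("A", 9, 8), stat("B", 4, 2)],
        ])
        assert a2.primary_nurse_id == "B"
        assert a2.category == Category.ONE_NURSE_CHARTED

    def test_exclusion_uses_step1_not_step2_prior_result(self):
        # one nurse charting across three consecutive windows: the middle
        # shift is voided (prior primary), and because the exclusion rule
        # consults *step-1* prior results, the third shift is voided too.
        a1, a2, a3 = self._run([
            [stat("A", 3, 2)], [stat("A", 4, 3)], [stat("A", 5, 4)],
        ])
        assert a1.primary_nurse_id == "A"
        assert a2.primary_nurse_id is None
        assert a3.primary_nurse_id is None
        assert a3.category == Category.ONLY_PRIOR_PRIMARY_CHARTED

    def test_no_exclusion_across_gap_in_shift_sequence(self):
        from shiftlink import shift_id_of
        first = shift_id_of(D(2019, 1, 1, 8))
        later = first.next().next()  # readmission after a one-window gap
        stats = {first: [stat("A", 3, 2)], later: [stat("A", 2, 1)]}
        a1, a2 = step2_select([first, later], stats, "P1")
        assert a2.primary_nurse_id == "A"

    def test_tie_categories(self):
        (a,) = self._run([[stat("A", 5, 10), stat("B", 5, 2)]])
        assert a.category == Category.TIE_BROKEN_BY_INTERVAL
        (b,) = self._run([[stat("A", 4, 6), stat("B", 4, 6)]])
        assert b.category == Category.TIE_NOT_BROKEN
        assert b.primary_nurse_id is None
        (c,) = self._run([[]])
        assert c.category == Category.NO_NURSE_CHARTED


class TestAssignAll:
    def test_single_nurse_throughout_stay_hand_trace(self):
        # nurse A charts in all three windows of one stay; exclusion voids
        # every window after the first
        events = events_frame([
            ("P1", "A", D(2018, 3, 5, 11)), ("P1", "A", D(2018, 3, 5, 15)),
            ("P1", "A", D(2018, 3, 5, 20)), ("P1", "A", D(2018, 3, 6, 2)),
            ("P1", "A", D(2018, 3, 6, 8)),
        ])
        stays = stays_frame([("P1", D(2018, 3, 5, 10), D(2018, 3, 6, 9))])
        result = assign_all(events, stays)
        nurses = [a.primary_nurse_id for a in result.assignments]
        cats = [a.category for a in result.assignments]
        assert nurses == ["A", None, None]
        assert cats == [Category.ONE_NURSE_CHARTED,
                        Category.ONLY_PRIOR_PRIMARY_CHARTED,
                        Category.ONLY_PRIOR_PRIMARY_CHARTED]

    def test_empty_events_yield_all_no_charter(self, empty_events):
        stays = stays_frame([("P1", D(2018, 3, 5, 10), D(2018, 3, 6, 9))])
        result = assign_all(empty_events, stays)
        assert all(a.category == Category.NO_NURSE_CHARTED
                   for a in result.assignments)

    def test_category_counts_partition_shifts(self):
        events = events_frame([
            ("P1", "A", D(2018, 3, 5, 11)), ("P1", "B", D(2018, 3, 5, 20)),
            ("P2", "C", D(2018, 3, 5, 12)),
        ])
        stays = stays_frame([
            ("P1", D(2018, 3, 5, 10), D(2018, 3, 6, 9)),
            ("P2", D(2018, 3, 5, 11), D(2018, 3, 5, 13)),
        ])
        result = assign_all(events, stays)
        assert result.summary["count"].sum() == len(result.assignments)
        for a in result.assignments:
            assert a.category.has_primary == (a.primary_nurse_id is not None)

    def test_invariance_to_event_order_and_duplication(self):
        events = events_frame([
            ("P1", "A", D(2018, 3, 5, 11)), ("P1", "B", D(2018, 3, 5, 11)),
            ("P1", "A", D(2018, 3, 5, 15)),
        ])
        stays = stays_frame([("P1", D(2018, 3, 5, 10), D(2018, 3, 6, 9))])
        base = assign_all(events, stays).assignments
        dup = assign_all(
            events.iloc[::-1].reset_index(drop=True)
            ._append(events, ignore_index=True),
            stays,
        ).assignments
        assert base == dup

    def test_matches_brute_force_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(2024)
        for _ in range(150):
            raw_events, raw_stays = random_small_fixture(rng)
            oracle = brute_force_assign(
                raw_events, [(p, i, o) for p, i, o in raw_stays]
            )
            events = events_frame(raw_events)
            stays = stays_frame(raw_stays)
            got = {
                (a.patient_id, a.shift.shift_date.isoformat(),
                 a.shift.period.value): (a.primary_nurse_id, int(a.category))
                for a in assign_all(events, stays).assignments
            }
            assert got == oracle
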