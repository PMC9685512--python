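"""The two-step primary-nurse selection algorithm and its six-way
outcome categorization.

Step 1 picks, per patient shift, the nurse with the highest count of unique
charting times, breaking count ties by the longest interval between first
and last charting times; a residual tie means no primary nurse (the
selection is fully deterministic — no randomness anywhere).  Step 2 re-runs
step 1 after excluding the step-1 primary of the patient's immediately
preceding contiguous shift, guarding against nurses who chart extensively
after their shift ends.  Exclusion always consults *step-1* prior results
and never crosses a gap in the patient's shift sequence (e.g. an ICU
readmission).
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import InternalInvariantError
from .records import Assignment, Category, NurseShiftStat, SelectionMode, ShiftID
from .shifts import (
    AttachedEvents,
    PatientShiftKey,
    attach_events,
    enumerate_all_patient_shifts,
)

_MODE_TO_CATEGORY = {
    SelectionMode.SOLE_CHARTER: Category.ONE_NURSE_CHARTED,
    SelectionMode.MAX_COUNT: Category.MOST_CHARTING_TIMES,
    SelectionMode.TIE_BROKEN: Category.TIE_BROKEN_BY_INTERVAL,
    SelectionMode.TIE_UNBROKEN: Category.TIE_NOT_BROKEN,
}


@dataclass(frozen=True)
class Step1Result:
    """Outcome of one argmax selection over a candidate set."""

    nurse_id: str | None
    mode: SelectionMode


def compute_stats(
    times_by_nurse: Mapping[str, Iterable[dt.datetime]],
) -> list[NurseShiftStat]:
    """Summarize one patient shift's deduplicated charting times per nurse."""
    stats = []
    for nurse_id in sorted(times_by_nurse):
        times = sorted(times_by_nurse[nurse_id])
        if not times:
            continue
        stats.append(NurseShiftStat(
            nurse_id=nurse_id,
            chart_count=len(times),
            first_time=times[0],
            last_time=times[-1],
        ))
    return stats


def step1_select(stats: Iterable[NurseShiftStat]) -> Step1Result:
    """Argmax by charting count, ties broken by charting interval.

    A tie on both count and interval yields no primary nurse rather than an
    arbitrary choice.
    """
    stats = list(stats)
    if not stats:
        return Step1Result(None, SelectionMode.NO_CHARTER)
    if len(stats) == 1:
        return Step1Result(stats[0].nurse_id, SelectionMode.SOLE_CHARTER)
    top_count = max(s.chart_count for s in stats)
    tied = [s for s in stats if s.chart_count == top_count]
    if len(tied) == 1:
        return Step1Result(tied[0].nurse_id, SelectionMode.MAX_COUNT)
    top_interval = max(s.interval for s in tied)
    winners = [s for s in tied if s.interval == top_interval]
    if len(winners) == 1:
        return Step1Result(winners[0].nurse_id, SelectionMode.TIE_BROKEN)
    return Step1Result(None, SelectionMode.TIE_UNBROKEN)


def categorize(
    stats: Iterable[NurseShiftStat],
    excluded_nurse_id: str | None,
    final: Step1Result,
) -> Category:
    """Map one shift's outcome to the six-way classification.

    Categories 1-3 and 5 describe the decisive comparison over the
    post-exclusion candidate set; 4 means nobody charted; 6 means the only
    charter was the excluded prior-shift primary.
    """
    stats = list(stats)
    if not stats:
        if final.mode is not SelectionMode.NO_CHARTER:
            raise InternalInvariantError("no stats but a selection was made")
        return Category.NO_NURSE_CHARTED
    candidates = [s for s in stats if s.nurse_id != excluded_nurse_id]
    if not candidates:
        if final.nurse_id is not None:
            raise InternalInvariantError("selection from empty candidate set")
        return Category.ONLY_PRIOR_PRIMARY_CHARTED
    try:
        return _MODE_TO_CATEGORY[final.mode]
    except KeyError:  # NO_CHARTER with non-empty candidates
        raise InternalInvariantError(
            f"selection mode {final.mode} inconsistent with candidate set"
        ) from None


def step2_select(
    ordered_shifts: list[ShiftID],
    stats_by_shift: Mapping[ShiftID, list[NurseShiftStat]],
    patient_id: str,
) -> list[Assignment]:
    """Apply prior-shift exclusion along one patient's shift sequence.

    ``ordered_shifts`` must be chronological.  For each shift, the step-1
    primary of the immediately preceding *contiguous* shift is removed from
    the candidate set and step 1 is re-run; after a gap no exclusion
    applies.
    """
    step1_by_shift = {
        shift: step1_select(stats_by_shift[shift]) for shift in ordered_shifts
    }
    present = {shift.index: shift for shift in ordered_shifts}
    assignments = []
    for shift in ordered_shifts:
        prior = present.get(shift.index - 1)
        excluded = step1_by_shift[prior].nurse_id if prior is not None else None
        stats = stats_by_shift[shift]
        final = step1_select(
            [s for s in stats if s.nurse_id != excluded]
        )
        category = categorize(stats, excluded, final)
        assignments.append(Assignment(
            patient_id=patient_id,
            shift=shift,
            primary_nurse_id=final.nurse_id,
            category=category,
            step1_nurse_id=step1_by_shift[shift].nurse_id,
        ))
    return assignments


@dataclass
class AssignmentResult:
    """Full-pipeline output: one assignment per enumerated patient shift."""

    assignments: list[Assignment]
    summary: pd.DataFrame
    n_unattached_events: int

    @property
    def by_key(self) -> dict[PatientShiftKey, Assignment]:
        return {a.key: a for a in self.assignments}


def summarize_categories(assignments: Iterable[Assignment]) -> pd.DataFrame:
    """Category counts and shares; the six counts partition all shifts."""
    assignments = list(assignments)
    total = len(assignments)
    counts = {c: 0 for c in Category}
    for a in assignments:
        counts[a.category] += 1
    return pd.DataFrame({
        "category": [int(c) for c in Category],
        "count": [counts[c] for c in Category],
        "share": [counts[c] / total if total else 0.0 for c in Category],
    })


def assign_all(events: pd.DataFrame, stays) -> AssignmentResult:
    """Run the full pipeline: enumerate shifts, attach events, select.

    Output is a pure function of (events, stays): invariant to row order
    and to duplicated event rows.
    """
    patient_shifts = enumerate_all_patient_shifts(stays)
    attached: AttachedEvents = attach_events(events, patient_shifts)
    by_patient: dict[str, list[ShiftID]] = {}
    for patient_id, shift in patient_shifts:
        by_patient.setdefault(patient_id, []).append(shift)
    assignments: list[Assignment] = []
    for patient_id in sorted(by_patient):
        shifts = sorted(by_patient[patient_id], key=lambda s: s.index)
        stats_by_shift = {
            shift: compute_stats(attached.times[(patient_id, shift)])
            for shift in shifts
        }
        assignments.extend(step2_select(shifts, stats_by_shift, patient_id))
    if len(assignments) != len(patient_shifts):
        raise InternalInvariantError(
            "assignment count does not match enumerated patient shifts"
        )
    return AssignmentResult(
        assignments=assignments,
        summary=summarize_categories(assignments),
        n_unattached_events=len(attached.unattached),
    )
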