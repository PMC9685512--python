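"""Shift-window arithmetic: timestamp binning, patient-shift enumeration,
and attachment of deduplicated charting events to patient shifts.

Consecutive 12-hour windows tile wall-clock time with no gaps or overlaps,
anchored at 07:00 and 19:00.  Windows are half-open at second resolution,
so "6:59:59 PM" is the last included second of a day shift.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import pandas as pd

from .records import ICUStay, PatientShift, SHIFT_ANCHOR, ShiftID

logger = logging.getLogger(__name__)

PatientShiftKey = tuple[str, ShiftID]


def shift_id_of(timestamp: dt.datetime) -> ShiftID:
    """Return the unique shift whose window contains ``timestamp``."""
    shifted = timestamp - SHIFT_ANCHOR
    index = shifted.date().toordinal() * 2 + (0 if shifted.hour < 12 else 1)
    return ShiftID.from_index(index)


def enumerate_patient_shifts(stay: ICUStay) -> list[PatientShift]:
    """Partition an ICU stay into the 12-h shift windows it overlaps.

    One PatientShift per window intersecting [icu_in, icu_out), in
    chronological order, each carrying the in-ICU overlap duration.
    """
    first = shift_id_of(stay.icu_in)
    # icu_out is exclusive: a stay ending exactly at a window boundary does
    # not spill into the next window.
    last = shift_id_of(stay.icu_out - dt.timedelta(seconds=1))
    out = []
    for index in range(first.index, last.index + 1):
        shift = ShiftID.from_index(index)
        overlap = (min(shift.window_end, stay.icu_out)
                   - max(shift.window_start, stay.icu_in))
        out.append(PatientShift(stay.patient_id, shift, overlap))
    return out


def enumerate_all_patient_shifts(
    stays: pd.DataFrame | list[ICUStay],
) -> dict[PatientShiftKey, PatientShift]:
    """Enumerate patient shifts for every stay, unioning overlapping stays.

    When two stays of one patient touch the same window the window appears
    once, with overlap measured on the union of the stay intervals.
    """
    if isinstance(stays, pd.DataFrame):
        stays = [
            ICUStay(r.patient_id, r.unit_id, r.icu_in.to_pydatetime(),
                    r.icu_out.to_pydatetime())
            for r in stays.itertuples(index=False)
        ]
    intervals: dict[PatientShiftKey, list[tuple[dt.datetime, dt.datetime]]] = {}
    for stay in stays:
        for ps in enumerate_patient_shifts(stay):
            lo = max(ps.window_start, stay.icu_in)
            hi = min(ps.window_end, stay.icu_out)
            intervals.setdefault(ps.key, []).append((lo, hi))
    out: dict[PatientShiftKey, PatientShift] = {}
    for key in sorted(intervals, key=lambda k: (k[0], k[1].index)):
        patient_id, shift = key
        overlap = _union_length(intervals[key])
        out[key] = PatientShift(patient_id, shift, overlap)
    return out


def _union_length(spans: list[tuple[dt.datetime, dt.datetime]]) -> dt.timedelta:
    total = dt.timedelta(0)
    cursor = None
    for lo, hi in sorted(spans):
        if cursor is None or lo > cursor:
            total += hi - lo
            cursor = hi
        elif hi > cursor:
            total += hi - cursor
            cursor = hi
    return total


@dataclass
class AttachedEvents:
    """Per-patient-shift, per-nurse sets of unique charting times.

    ``times[key][nurse_id]`` is a sorted tuple of distinct datetimes.
    Events whose (patient, window) matches no enumerated patient shift are
    returned in ``unattached`` untouched.
    """

    times: dict[PatientShiftKey, dict[str, tuple[dt.datetime, ...]]]
    unattached: pd.DataFrame = field(repr=False, default=None)


def attach_events(
    events: pd.DataFrame,
    patient_shifts: dict[PatientShiftKey, PatientShift],
) -> AttachedEvents:
    """Attach events to patient shifts and collapse duplicate timestamps.

    An event lands on patient shift (p, s) iff its patient matches and its
    timestamp falls in s's window; the shift must exist (events are *not*
    clipped to the ICU-stay interval, so charting during the window but
    before admission or after discharge still counts).  Within one
    (patient shift, nurse), identical seconds collapse to one charting
    time.  Output is invariant to event order and to duplicated rows.
    """
    times: dict[PatientShiftKey, dict[str, set]] = {
        key: {} for key in patient_shifts
    }
    unattached_idx: list[int] = []
    if len(events):
        shifted = events["timestamp"] - pd.Timedelta(SHIFT_ANCHOR)
        ordinals = shifted.dt.date.map(dt.date.toordinal)
        indices = ordinals * 2 + (shifted.dt.hour >= 12).astype(int)
        for pos, (patient_id, index, nurse_id, ts) in enumerate(zip(
            events["patient_id"], indices, events["nurse_id"],
            events["timestamp"],
        )):
            key = (patient_id, ShiftID.from_index(int(index)))
            bucket = times.get(key)
            if bucket is None:
                unattached_idx.append(pos)
                continue
            bucket.setdefault(nurse_id, set()).add(ts.to_pydatetime())
    if unattached_idx:
        logger.info("%d event(s) matched no patient shift", len(unattached_idx))
    unattached = (events.iloc[unattached_idx].reset_index(drop=True)
                  if len(events) else events)
    frozen = {
        key: {nurse: tuple(sorted(ts)) for nurse, ts in sorted(by_nurse.items())}
        for key, by_nurse in times.items()
    }
    return AttachedEvents(times=frozen, unattached=unattached)
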