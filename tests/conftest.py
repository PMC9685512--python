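"""Shared fixtures and builders for the test suite."""
from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from shiftlink import Assignment, Category, ReviewLabel, ShiftID, ShiftPeriod

EVENT_COLUMNS = ["patient_id", "nurse_id", "timestamp", "kind"]
STAY_COLUMNS = ["patient_id", "unit_id", "icu_in", "icu_out"]


def events_frame(rows) -> pd.DataFrame:
    """Rows of (patient_id, nurse_id, timestamp[, kind]) -> events table."""
    records = []
    for row in rows:
        patient_id, nurse_id, ts = row[:3]
        kind = row[3] if len(row) > 3 else "assessment"
        records.append({"patient_id": patient_id, "nurse_id": nurse_id,
                        "timestamp": pd.Timestamp(ts), "kind": kind})
    frame = pd.DataFrame(records, columns=EVENT_COLUMNS)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame


def stays_frame(rows) -> pd.DataFrame:
    """Rows of (patient_id, icu_in, icu_out[, unit_id]) -> stays table."""
    records = []
    for row in rows:
        patient_id, icu_in, icu_out = row[:3]
        unit = row[3] if len(row) > 3 else "U0"
        records.append({"patient_id": patient_id, "unit_id": unit,
                        "icu_in": pd.Timestamp(icu_in),
                        "icu_out": pd.Timestamp(icu_out)})
    frame = pd.DataFrame(records, columns=STAY_COLUMNS)
    frame["icu_in"] = pd.to_datetime(frame["icu_in"])
    frame["icu_out"] = pd.to_datetime(frame["icu_out"])
    return frame


def day_shift(date: str) -> ShiftID:
    return ShiftID(dt.date.fromisoformat(date), ShiftPeriod.DAY)


def chart_review_scenario(tp: int = 184, fp: int = 11, fn: int = 3,
                          tn: int = 2):
    """Assignments plus review labels realizing a given confusion matrix.

    One patient per reviewed shift, all on the same day shift; positive
    algorithm calls are category 1, negative calls category 4.
    """
    shift = day_shift("2019-02-01")
    assignments: list[Assignment] = []
    labels: list[ReviewLabel] = []
    i = 0
    for _ in range(tp):
        pid = f"P{i:04d}"; i += 1
        assignments.append(Assignment(pid, shift, f"RN{i}",
                                      Category.ONE_NURSE_CHARTED))
        labels.append(ReviewLabel(pid, shift, f"RN{i}"))
    for j in range(fp):
        pid = f"P{i:04d}"; i += 1
        assignments.append(Assignment(pid, shift, f"RN{i}",
                                      Category.ONE_NURSE_CHARTED))
        # review disagrees: different nurse for some, no nurse for the rest
        labels.append(ReviewLabel(pid, shift,
                                  f"OTHER{i}" if j % 2 == 0 else None))
    for _ in range(fn):
        pid = f"P{i:04d}"; i += 1
        assignments.append(Assignment(pid, shift, None,
                                      Category.NO_NURSE_CHARTED))
        labels.append(ReviewLabel(pid, shift, f"RN{i}"))
    for _ in range(tn):
        pid = f"P{i:04d}"; i += 1
        assignments.append(Assignment(pid, shift, None,
                                      Category.NO_NURSE_CHARTED))
        labels.append(ReviewLabel(pid, shift, None))
    return assignments, labels


@pytest.fixture
def empty_events() -> pd.DataFrame:
    return events_frame([])
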