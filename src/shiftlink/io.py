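"""Readers and writers for the package's tabular interchange formats.

All files are comma-separated UTF-8 with a header row and ISO 8601
timestamps.  Schemas:

* ``events.csv``      -- patient_id, nurse_id, timestamp, kind
* ``stays.csv``       -- patient_id, unit_id, icu_in, icu_out
* ``assignments.csv`` -- patient_id, shift_date, period, primary_nurse_id, category
* ``review.csv``      -- patient_id, shift_date, period, reviewed_nurse_id

An empty ``primary_nurse_id`` / ``reviewed_nurse_id`` field is the
none-marker.  Reading is loss-free and order-preserving; duplicate event
rows are retained (deduplication is an algorithm step, not an I/O step).
"""
from __future__ import annotations

import datetime as dt
import logging
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import SchemaError
from .records import (
    Assignment,
    Category,
    EventKind,
    ICUStay,
    ReviewLabel,
    ShiftID,
    ShiftPeriod,
)

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["patient_id", "nurse_id", "timestamp", "kind"]
STAY_COLUMNS = ["patient_id", "unit_id", "icu_in", "icu_out"]
ASSIGNMENT_COLUMNS = ["patient_id", "shift_date", "period",
                      "primary_nurse_id", "category"]
REVIEW_COLUMNS = ["patient_id", "shift_date", "period", "reviewed_nurse_id"]

_KINDS = {k.value for k in EventKind}
_PERIODS = {p.value for p in ShiftPeriod}


def _read_csv(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", path=str(path))
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"missing required column(s): {', '.join(missing)}",
            path=str(path), line=1,
        )
    return frame


def _parse_timestamps(frame: pd.DataFrame, column: str,
                      path: str | Path) -> pd.Series:
    parsed = pd.to_datetime(frame[column], format="ISO8601", errors="coerce")
    bad = parsed.isna() | (frame[column].str.strip() == "")
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"unparseable {column} {frame[column].iloc[row]!r}",
            path=str(path), line=row + 2,  # header is line 1
        )
    return parsed.dt.floor("s")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a charting-event table.

    Returns a DataFrame with columns ``patient_id``, ``nurse_id``,
    ``timestamp`` (datetime64, second resolution) and ``kind``.  Duplicate
    rows are retained.
    """
    frame = _read_csv(path, EVENT_COLUMNS)
    frame = frame[EVENT_COLUMNS].copy()
    for col in ("patient_id", "nurse_id"):
        empty = frame[col].str.strip() == ""
        if empty.any():
            raise SchemaError(f"empty {col}", path=str(path),
                              line=int(empty.idxmax()) + 2)
    frame["timestamp"] = _parse_timestamps(frame, "timestamp", path)
    unknown = ~frame["kind"].isin(_KINDS)
    if unknown.any():
        row = int(unknown.idxmax())
        raise SchemaError(
            f"unknown kind {frame['kind'].iloc[row]!r} "
            f"(expected one of {sorted(_KINDS)})",
            path=str(path), line=row + 2,
        )
    return frame


def read_stays(path: str | Path) -> pd.DataFrame:
    """Read an ICU-stay table; enforces ``icu_in < icu_out`` per row.

    Overlapping stays for one patient are legal but logged as a warning;
    patient-shift enumeration unions their windows downstream.
    """
    frame = _read_csv(path, STAY_COLUMNS)
    frame = frame[STAY_COLUMNS].copy()
    frame["icu_in"] = _parse_timestamps(frame, "icu_in", path)
    frame["icu_out"] = _parse_timestamps(frame, "icu_out", path)
    bad = frame["icu_out"] <= frame["icu_in"]
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"icu_out <= icu_in for patient {frame['patient_id'].iloc[row]!r}",
            path=str(path), line=row + 2,
        )
    _warn_overlapping_stays(frame)
    return frame


def _warn_overlapping_stays(stays: pd.DataFrame) -> None:
    for patient_id, group in stays.groupby("patient_id", sort=False):
        if len(group) < 2:
            continue
        ordered = group.sort_values("icu_in")
        overlap = (ordered["icu_in"].iloc[1:].values
                   < ordered["icu_out"].iloc[:-1].values)
        if overlap.any():
            logger.warning(
                "patient %s has overlapping ICU stays; both retained",
                patient_id,
            )


def stays_to_records(frame: pd.DataFrame) -> list[ICUStay]:
    return [
        ICUStay(row.patient_id, row.unit_id,
                row.icu_in.to_pydatetime(), row.icu_out.to_pydatetime())
        for row in frame.itertuples(index=False)
    ]


def _shift_from_fields(date_text: str, period_text: str,
                       path: str | Path, line: int) -> ShiftID:
    try:
        date = dt.date.fromisoformat(date_text)
    except ValueError as exc:
        raise SchemaError(f"bad shift_date {date_text!r}: {exc}",
                          path=str(path), line=line) from exc
    if period_text not in _PERIODS:
        raise SchemaError(
            f"bad period {period_text!r} (expected day or night)",
            path=str(path), line=line,
        )
    return ShiftID(date, ShiftPeriod(period_text))


def write_assignments(assignments: Iterable[Assignment],
                      path: str | Path) -> None:
    """Serialize assignments; raises on duplicate patient-shift keys."""
    rows = []
    seen: set[tuple] = set()
    for a in assignments:
        if a.key in seen:
            raise SchemaError(
                f"two assignments for patient shift "
                f"({a.patient_id}, {a.shift.shift_date}, {a.shift.period.value})"
            )
        seen.add(a.key)
        rows.append({
            "patient_id": a.patient_id,
            "shift_date": a.shift.shift_date.isoformat(),
            "period": a.shift.period.value,
            "primary_nurse_id": a.primary_nurse_id or "",
            "category": int(a.category),
        })
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(path, index=False)


def read_assignments(path: str | Path) -> list[Assignment]:
    frame = _read_csv(path, ASSIGNMENT_COLUMNS)
    out: list[Assignment] = []
    seen: set[tuple] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2
        shift = _shift_from_fields(row.shift_date, row.period, path, line)
        try:
            category = Category(int(row.category))
        except ValueError as exc:
            raise SchemaError(f"bad category {row.category!r}",
                              path=str(path), line=line) from exc
        nurse = row.primary_nurse_id or None
        try:
            assignment = Assignment(row.patient_id, shift, nurse, category)
        except ValueError as exc:
            raise SchemaError(str(exc), path=str(path), line=line) from exc
        if assignment.key in seen:
            raise SchemaError("duplicate patient-shift key",
                              path=str(path), line=line)
        seen.add(assignment.key)
        out.append(assignment)
    return out


def read_review(path: str | Path) -> list[ReviewLabel]:
    """Read chart-review labels; empty reviewed_nurse_id means 'no nurse'."""
    frame = _read_csv(path, REVIEW_COLUMNS)
    out: list[ReviewLabel] = []
    seen: set[tuple] = set()
    for i, row in enumerate(frame.itertuples(index=False)):
        line = i + 2
        shift = _shift_from_fields(row.shift_date, row.period, path, line)
        label = ReviewLabel(row.patient_id, shift,
                            row.reviewed_nurse_id or None)
        if label.key in seen:
            raise SchemaError("duplicate review label for patient shift",
                              path=str(path), line=line)
        seen.add(label.key)
        out.append(label)
    return out


def write_review(labels: Iterable[ReviewLabel], path: str | Path) -> None:
    rows = [{
        "patient_id": lab.patient_id,
        "shift_date": lab.shift.shift_date.isoformat(),
        "period": lab.shift.period.value,
        "reviewed_nurse_id": lab.reviewed_nurse_id or "",
    } for lab in labels]
    pd.DataFrame(rows, columns=REVIEW_COLUMNS).to_csv(path, index=False)


def events_frame(events: Iterable) -> pd.DataFrame:
    """Build an events DataFrame from ChartingEvent records (test helper)."""
    rows = [{
        "patient_id": e.patient_id,
        "nurse_id": e.nurse_id,
        "timestamp": pd.Timestamp(e.timestamp),
        "kind": e.kind.value if isinstance(e.kind, EventKind) else e.kind,
    } for e in events]
    frame = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    return frame
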