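"""Typed domain records for nurse-to-patient assignment inference.

All timestamps in this package are naive local wall-clock datetimes with
second resolution.  Shift boundaries (07:00 and 19:00) are wall-clock
anchors, so no timezone arithmetic is performed anywhere: on a daylight
saving transition night the elapsed duration of the night window differs
from 12 hours, but its wall-clock boundaries do not move.
"""
from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field

DAY_START = dt.time(7, 0, 0)
NIGHT_START = dt.time(19, 0, 0)
SHIFT_ANCHOR = dt.timedelta(hours=7)


class EventKind(str, enum.Enum):
    """Charting domains that leave an electronic signature."""

    ASSESSMENT = "assessment"
    MEDICATION = "medication"


class ShiftPeriod(str, enum.Enum):
    DAY = "day"
    NIGHT = "night"


class SelectionMode(str, enum.Enum):
    """How (or why not) the argmax selection resolved for one candidate set."""

    SOLE_CHARTER = "sole_charter"    # only one nurse in the candidate set
    MAX_COUNT = "max_count"          # unique maximum charting count
    TIE_BROKEN = "tie_broken"        # count tie broken by charting interval
    TIE_UNBROKEN = "tie_unbroken"    # tie on count and interval -> no nurse
    NO_CHARTER = "no_charter"        # empty candidate set


class Category(enum.IntEnum):
    """Six-way outcome classification of a patient shift.

    1-3 always carry a named primary nurse; 4-6 never do.  Categories 1-3
    and 5 describe the decisive comparison over the post-exclusion candidate
    set; 6 means the only charter was the prior shift's primary and was
    excluded; 4 means nobody charted at all.
    """

    ONE_NURSE_CHARTED = 1
    MOST_CHARTING_TIMES = 2
    TIE_BROKEN_BY_INTERVAL = 3
    NO_NURSE_CHARTED = 4
    TIE_NOT_BROKEN = 5
    ONLY_PRIOR_PRIMARY_CHARTED = 6

    @property
    def has_primary(self) -> bool:
        return self.value in (1, 2, 3)


@dataclass(frozen=True, order=True)
class ShiftID:
    """One 12-hour nursing shift, labeled by its start date.

    The day shift covers [07:00:00, 19:00:00) of ``shift_date``; the night
    shift covers [19:00:00 of ``shift_date``, 07:00:00 of the next date).
    Hours 00:00-06:59:59 therefore belong to the *previous* date's night
    shift.  Ordering is chronological: (shift_date, day) < (shift_date,
    night) < (next date, day).
    """

    shift_date: dt.date
    period: ShiftPeriod

    @property
    def index(self) -> int:
        """Position in the global sequence of consecutive 12-h windows."""
        return self.shift_date.toordinal() * 2 + (
            0 if self.period is ShiftPeriod.DAY else 1
        )

    @classmethod
    def from_index(cls, index: int) -> "ShiftID":
        date = dt.date.fromordinal(index // 2)
        period = ShiftPeriod.DAY if index % 2 == 0 else ShiftPeriod.NIGHT
        return cls(date, period)

    @property
    def window_start(self) -> dt.datetime:
        start_time = DAY_START if self.period is ShiftPeriod.DAY else NIGHT_START
        return dt.datetime.combine(self.shift_date, start_time)

    @property
    def window_end(self) -> dt.datetime:
        if self.period is ShiftPeriod.DAY:
            return dt.datetime.combine(self.shift_date, NIGHT_START)
        return dt.datetime.combine(
            self.shift_date + dt.timedelta(days=1), DAY_START
        )

    def prev(self) -> "ShiftID":
        return ShiftID.from_index(self.index - 1)

    def next(self) -> "ShiftID":
        return ShiftID.from_index(self.index + 1)


@dataclass(frozen=True)
class ChartingEvent:
    """One timestamped electronic signature linking a nurse to a patient."""

    patient_id: str
    nurse_id: str
    timestamp: dt.datetime
    kind: EventKind

    def __post_init__(self) -> None:
        if not self.patient_id or not self.nurse_id:
            raise ValueError("patient_id and nurse_id must be non-empty")
        if self.timestamp.microsecond:
            raise ValueError("timestamps must have second resolution")


@dataclass(frozen=True)
class ICUStay:
    """A patient's contiguous interval in one ICU."""

    patient_id: str
    unit_id: str
    icu_in: dt.datetime
    icu_out: dt.datetime

    def __post_init__(self) -> None:
        if self.icu_out <= self.icu_in:
            raise ValueError(
                f"stay for patient {self.patient_id!r} has "
                f"icu_out <= icu_in ({self.icu_out} <= {self.icu_in})"
            )


@dataclass(frozen=True)
class PatientShift:
    """Unit of analysis: one patient crossed with one 12-hour shift window."""

    patient_id: str
    shift: ShiftID
    icu_overlap: dt.timedelta

    @property
    def key(self) -> tuple[str, "ShiftID"]:
        return (self.patient_id, self.shift)

    @property
    def window_start(self) -> dt.datetime:
        return self.shift.window_start

    @property
    def window_end(self) -> dt.datetime:
        return self.shift.window_end


@dataclass(frozen=True)
class NurseShiftStat:
    """Per-(patient shift, nurse) charting summary: the algorithm's two inputs.

    ``chart_count`` counts *unique* charting seconds (multiple signatures at
    one second collapse); ``interval`` is the span between the nurse's first
    and last charting times within the shift window.
    """

    nurse_id: str
    chart_count: int
    first_time: dt.datetime
    last_time: dt.datetime

    def __post_init__(self) -> None:
        if self.chart_count < 1:
            raise ValueError("chart_count must be >= 1")
        if self.last_time < self.first_time:
            raise ValueError("last_time precedes first_time")
        if self.chart_count == 1 and self.interval:
            raise ValueError("single charting time implies zero interval")

    @property
    def interval(self) -> dt.timedelta:
        return self.last_time - self.first_time


@dataclass(frozen=True)
class Assignment:
    """Final algorithm output for one patient shift.

    ``step1_nurse_id`` retains the pre-exclusion (step-1) selection for
    audit; it is not part of the serialized record and is excluded from
    equality comparisons.
    """

    patient_id: str
    shift: ShiftID
    primary_nurse_id: str | None
    category: Category
    step1_nurse_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.category.has_primary != (self.primary_nurse_id is not None):
            raise ValueError(
                f"category {int(self.category)} inconsistent with "
                f"primary_nurse_id={self.primary_nurse_id!r}"
            )

    @property
    def key(self) -> tuple[str, ShiftID]:
        return (self.patient_id, self.shift)


@dataclass(frozen=True)
class ReviewLabel:
    """Chart-review reference standard for one patient shift."""

    patient_id: str
    shift: ShiftID
    reviewed_nurse_id: str | None

    @property
    def key(self) -> tuple[str, ShiftID]:
        return (self.patient_id, self.shift)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts of algorithm calls against chart-review labels."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its exact binomial confidence interval."""

    point: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0):
            raise ValueError("interval must bracket the point within [0, 1]")
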