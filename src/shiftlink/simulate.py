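"""Synthetic EHR charting-metadata generator with known ground truth.

The simulator emulates the three input tables (stays, events, chart-review
truth) for a multi-unit ICU: each patient gets one ICU stay with a
log-normal length of stay, each patient shift gets a scheduled primary
nurse from the unit roster (never the same nurse as the adjacent prior
shift, mirroring 12-hour scheduling), and the primary's charting times are
a Poisson process over the shift window intersected with the stay, with a
guaranteed start-of-care assessment signature.

Documented failure modes of metadata-based assignment inference are
injected as contamination scenarios:

* ``cross_coverage`` -- a second nurse charts a few times in a short span
  (breaks, emergencies), distinguishable by both count and interval;
* ``late_charting``  -- the outgoing primary keeps charting into the first
  hour of the next shift, the mechanism the prior-shift exclusion guards
  against;
* ``orientee``       -- a nurse in training co-signs at exactly the
  primary's charting times, producing an unbreakable tie;
* ``no_documentation`` -- a very short boundary shift (admission late in
  the window or discharge early in it) leaves no signatures at all.

All draws run through counter-based substreams keyed by (seed, patient,
shift window), so regeneration is order-independent and byte-reproducible.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .records import Assignment, ICUStay, ShiftID
from .shifts import PatientShiftKey, enumerate_patient_shifts

BASE_DATE = dt.datetime(2019, 1, 1)
TRUTH_COLUMNS = ["patient_id", "shift_date", "period", "true_nurse_id",
                 "scenario"]


class SimConfig(BaseModel):
    """Simulation parameters; defaults describe a plausible ICU.

    Rates are events per hour; the length-of-stay distribution is
    log-normal in hours (defaults give a median stay of about two days
    with a long right tail and occasional very short stays).
    """

    n_units: int = Field(default=2, ge=1)
    nurses_per_unit: int = Field(default=12, ge=2)
    n_patients: int = Field(default=50, ge=1)
    horizon_days: int = Field(default=30, ge=1)
    los_log_mean: float = 3.87   # log-hours; exp(3.87) ~ 48 h median
    los_log_sigma: float = Field(default=1.0, gt=0)
    assessment_rate: float = Field(default=2.0, gt=0)
    medication_rate: float = Field(default=0.5, gt=0)
    p_cross_coverage: float = Field(default=0.15, ge=0, le=1)
    lambda_cross: float = Field(default=2.0, ge=0)
    p_late_charting: float = Field(default=0.10, ge=0, le=1)
    lambda_late: float = Field(default=3.0, ge=0)
    p_orientee: float = Field(default=0.02, ge=0, le=1)
    p_no_documentation: float = Field(default=0.5, ge=0, le=1)
    short_shift_hours: float = Field(default=2.0, gt=0)
    seed: int = 0

    @field_validator("nurses_per_unit")
    @classmethod
    def _roster_large_enough(cls, v: int) -> int:
        if v < 2:
            raise ValueError(
                "roster too small to avoid adjacent-shift repeats"
            )
        return v

    def clean(self, **overrides) -> "SimConfig":
        """Copy with every contamination probability set to zero."""
        return self.model_copy(update={
            "p_cross_coverage": 0.0,
            "p_late_charting": 0.0,
            "p_orientee": 0.0,
            "p_no_documentation": 0.0,
            **overrides,
        })

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a key-value mapping")
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


@dataclass
class SimBundle:
    """Simulator output: the three tables plus the generating config."""

    stays: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig


def _floor_second(ts: dt.datetime) -> dt.datetime:
    return ts.replace(microsecond=0)


def _uniform_times(rng, start: dt.datetime, duration_s: float,
                   n: int) -> list[dt.datetime]:
    offsets = rng.uniform(0, duration_s, size=n)
    return [_floor_second(start + dt.timedelta(seconds=float(o)))
            for o in offsets]


def simulate(config: SimConfig) -> SimBundle:
    """Generate stays, charting events, and per-shift ground truth."""
    rosters = [
        [f"N{u:02d}{i:02d}" for i in range(config.nurses_per_unit)]
        for u in range(config.n_units)
    ]
    stay_rows = []
    event_rows: list[dict] = []
    truth_nurse: dict[PatientShiftKey, str | None] = {}
    tags: dict[PatientShiftKey, set[str]] = {}

    for pidx in range(config.n_patients):
        patient_id = f"P{pidx:05d}"
        rng_p = np.random.default_rng([config.seed, 1, pidx])
        unit = int(rng_p.integers(config.n_units))
        roster = rosters[unit]
        icu_in = _floor_second(
            BASE_DATE + dt.timedelta(
                seconds=float(rng_p.uniform(0, config.horizon_days * 86400))
            )
        )
        los_hours = max(
            float(rng_p.lognormal(config.los_log_mean, config.los_log_sigma)),
            1 / 60,
        )
        icu_out = _floor_second(icu_in + dt.timedelta(hours=los_hours))
        if icu_out <= icu_in:
            icu_out = icu_in + dt.timedelta(minutes=1)
        stay = ICUStay(patient_id, f"U{unit:02d}", icu_in, icu_out)
        stay_rows.append({
            "patient_id": patient_id, "unit_id": stay.unit_id,
            "icu_in": icu_in, "icu_out": icu_out,
        })

        shifts = enumerate_patient_shifts(stay)
        prev_primary: str | None = None
        for ps in shifts:
            key = ps.key
            tags.setdefault(key, set())
            rng_s = np.random.default_rng(
                [config.seed, 2, pidx, ps.shift.index]
            )
            candidates = [n for n in roster if n != prev_primary]
            primary = candidates[int(rng_s.integers(len(candidates)))]
            prev_primary = primary

            lo = max(ps.window_start, icu_in)
            hi = min(ps.window_end, icu_out)
            dur_s = (hi - lo).total_seconds()
            dur_h = dur_s / 3600.0

            if (dur_h < config.short_shift_hours
                    and rng_s.random() < config.p_no_documentation):
                truth_nurse[key] = None
                tags[key].add("no_documentation")
                continue
            truth_nurse[key] = primary

            # Guaranteed start-of-care signature, then Poisson charting.
            times = [(_floor_second(lo), "assessment")]
            n_a = int(rng_s.poisson(config.assessment_rate * dur_h))
            n_m = int(rng_s.poisson(config.medication_rate * dur_h))
            times += [(t, "assessment")
                      for t in _uniform_times(rng_s, lo, dur_s, n_a)]
            times += [(t, "medication")
                      for t in _uniform_times(rng_s, lo, dur_s, n_m)]
            for t, kind in times:
                event_rows.append({
                    "patient_id": patient_id, "nurse_id": primary,
                    "timestamp": t, "kind": kind,
                })

            orientee: str | None = None
            if rng_s.random() < config.p_orientee:
                others = [n for n in roster if n != primary]
                orientee = others[int(rng_s.integers(len(others)))]
                for t, kind in times:
                    event_rows.append({
                        "patient_id": patient_id, "nurse_id": orientee,
                        "timestamp": t, "kind": kind,
                    })
                tags[key].add("orientee")

            if rng_s.random() < config.p_cross_coverage:
                others = [n for n in roster
                          if n != primary and n != orientee]
                cross = others[int(rng_s.integers(len(others)))]
                k = int(rng_s.poisson(config.lambda_cross))
                if k:
                    center = lo + dt.timedelta(
                        seconds=float(rng_s.uniform(0, dur_s))
                    )
                    span_lo = max(lo, center - dt.timedelta(minutes=15))
                    span_s = min(
                        1800.0,
                        (hi - span_lo).total_seconds() or 1.0,
                    )
                    for t in _uniform_times(rng_s, span_lo, span_s, k):
                        event_rows.append({
                            "patient_id": patient_id, "nurse_id": cross,
                            "timestamp": min(t, hi - dt.timedelta(seconds=1)),
                            "kind": "assessment",
                        })
                    tags[key].add("cross_coverage")

            next_key = (patient_id, ps.shift.next())
            has_next = ps.shift.index + 1 <= shifts[-1].shift.index
            if has_next and rng_s.random() < config.p_late_charting:
                m = int(rng_s.poisson(config.lambda_late))
                if m:
                    nxt_start = ps.shift.next().window_start
                    for t in _uniform_times(rng_s, nxt_start, 3600.0, m):
                        event_rows.append({
                            "patient_id": patient_id, "nurse_id": primary,
                            "timestamp": t, "kind": "assessment",
                        })
                    tags.setdefault(next_key, set()).add("late_charting")

    events = pd.DataFrame(
        event_rows,
        columns=["patient_id", "nurse_id", "timestamp", "kind"],
    )
    events["timestamp"] = pd.to_datetime(events["timestamp"])
    events = events.sort_values(
        ["patient_id", "timestamp", "nurse_id", "kind"]
    ).reset_index(drop=True)

    truth = pd.DataFrame([
        {
            "patient_id": patient_id,
            "shift_date": shift.shift_date.isoformat(),
            "period": shift.period.value,
            "true_nurse_id": truth_nurse[(patient_id, shift)] or "",
            "scenario": "+".join(sorted(tags[(patient_id, shift)])) or "clean",
        }
        for (patient_id, shift) in sorted(
            truth_nurse, key=lambda k: (k[0], k[1].index)
        )
    ], columns=TRUTH_COLUMNS)

    stays = pd.DataFrame(stay_rows,
                         columns=["patient_id", "unit_id", "icu_in", "icu_out"])
    return SimBundle(stays=stays, events=events, truth=truth, config=config)


def truth_records(truth: pd.DataFrame) -> dict[PatientShiftKey, tuple]:
    """Index a truth table by patient-shift key -> (nurse or None, scenario)."""
    from .records import ShiftPeriod

    out = {}
    for row in truth.itertuples(index=False):
        shift = ShiftID(dt.date.fromisoformat(row.shift_date),
                        ShiftPeriod(row.period))
        out[(row.patient_id, shift)] = (row.true_nurse_id or None,
                                        row.scenario)
    return out


@dataclass
class RecoveryReport:
    """Agreement between algorithm output and simulated ground truth."""

    overall: float
    n: int
    by_scenario: pd.DataFrame


def recovery_report(assignments: Iterable[Assignment],
                    truth: pd.DataFrame) -> RecoveryReport:
    """Share of shifts where the algorithm output equals the ground truth.

    A named nurse matches on identity; an algorithm 'none' matches a truth
    'none'.  The assignment and truth key spaces must coincide.
    """
    truth_map = truth_records(truth)
    by_key = {a.key: a for a in assignments}
    if set(by_key) != set(truth_map):
        missing = set(truth_map) ^ set(by_key)
        raise KeyError(
            f"assignments and truth cover different patient shifts "
            f"({len(missing)} mismatched keys)"
        )
    rows = []
    for key, (true_nurse, scenario) in truth_map.items():
        rows.append({
            "scenario": scenario,
            "recovered": by_key[key].primary_nurse_id == true_nurse,
        })
    frame = pd.DataFrame(rows)
    by_scenario = (
        frame.groupby("scenario")["recovered"]
        .agg(n="size", recovery="mean")
        .reset_index()
    )
    return RecoveryReport(
        overall=float(frame["recovered"].mean()),
        n=len(frame),
        by_scenario=by_scenario,
    )


def write_bundle(bundle: SimBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write events.csv, stays.csv and truth.csv under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (("events", bundle.events), ("stays", bundle.stays),
                        ("truth", bundle.truth)):
        path = out_dir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
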