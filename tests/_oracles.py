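"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's shift/selection code paths: windows
are re-derived by stepping wall-clock boundaries, selection by full sorting
of (count, interval) tuples, exclusion by literal re-enumeration, and
Clopper-Pearson intervals by bisecting binomial tail sums.
"""
from __future__ import annotations

import datetime as dt
from collections import defaultdict

import numpy as np
from scipy.stats import binom

TWELVE_H = dt.timedelta(hours=12)


def windows_overlapping(lo: dt.datetime, hi: dt.datetime):
    """All 12-h windows (anchored 07:00/19:00) intersecting [lo, hi)."""
    start = dt.datetime.combine(lo.date() - dt.timedelta(days=1),
                                dt.time(7, 0, 0))
    wins = []
    while start < hi:
        end = start + TWELVE_H
        if end > lo:
            wins.append(start)
        start = end
    return wins


def _label(window_start: dt.datetime):
    period = "day" if window_start.hour == 7 else "night"
    return (window_start.date().isoformat(), period)


def _top_by_sort(stats: dict[str, set]) -> str | None:
    """Full-sort selection: best (count, interval); residual tie -> None."""
    ranked = sorted(
        (
            (len(times), (max(times) - min(times)).total_seconds(), nurse)
            for nurse, times in stats.items()
        ),
        reverse=True,
    )
    if not ranked:
        return None
    if len(ranked) > 1 and ranked[0][:2] == ranked[1][:2]:
        return None
    return ranked[0][2]


def brute_force_assign(events, stays):
    """Reference two-step assignment.

    ``events``: iterable of (patient_id, nurse_id, timestamp);
    ``stays``: iterable of (patient_id, icu_in, icu_out).
    Returns {(patient_id, date_iso, period): (nurse_or_None, category)}.
    """
    windows_by_patient: dict[str, set] = defaultdict(set)
    for patient_id, icu_in, icu_out in stays:
        for w in windows_overlapping(icu_in, icu_out):
            windows_by_patient[patient_id].add(w)

    times: dict[tuple, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    for patient_id, nurse_id, ts in events:
        for w in windows_by_patient.get(patient_id, ()):
            if w <= ts < w + TWELVE_H:
                times[(patient_id, w)][nurse_id].add(ts)

    out = {}
    for patient_id, windows in windows_by_patient.items():
        step1 = {
            w: _top_by_sort(times.get((patient_id, w), {})) for w in windows
        }
        for w in sorted(windows):
            stats = times.get((patient_id, w), {})
            excluded = step1[w - TWELVE_H] if (w - TWELVE_H) in windows else None
            candidates = {n: t for n, t in stats.items() if n != excluded}
            if not stats:
                result = (None, 4)
            elif not candidates:
                result = (None, 6)
            elif len(candidates) == 1:
                result = (next(iter(candidates)), 1)
            else:
                winner = _top_by_sort(candidates)
                if winner is None:
                    result = (None, 5)
                else:
                    top = len(candidates[winner])
                    others = [len(t) for n, t in candidates.items()
                              if n != winner]
                    result = (winner, 2 if top > max(others) else 3)
            out[(patient_id, *_label(w))] = result
    return out


def cp_tail_sum_grid(xs, ns, alpha: float = 0.05, iters: int = 60):
    """Clopper-Pearson bounds by bisecting binomial tail sums.

    Vectorized over arrays of (successes, n); returns (low, high) arrays.
    """
    xs = np.asarray(xs, dtype=float)
    ns = np.asarray(ns, dtype=float)

    lo, hi = np.zeros_like(xs), np.ones_like(xs)
    for _ in range(iters):
        mid = (lo + hi) / 2
        # P(X >= x | p) grows with p; the lower bound solves it = alpha/2
        too_high = binom.sf(xs - 1, ns, mid) >= alpha / 2
        hi = np.where(too_high, mid, hi)
        lo = np.where(too_high, lo, mid)
    low = np.where(xs == 0, 0.0, (lo + hi) / 2)

    lo, hi = np.zeros_like(xs), np.ones_like(xs)
    for _ in range(iters):
        mid = (lo + hi) / 2
        # P(X <= x | p) shrinks with p; the upper bound solves it = alpha/2
        too_low = binom.cdf(xs, ns, mid) >= alpha / 2
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    high = np.where(xs == ns, 1.0, (lo + hi) / 2)
    return low, high


def random_small_fixture(rng: np.random.Generator):
    """A random stay plus <=20 coarse-grid charting events of <=6 nurses.

    The half-hour time grid makes count and interval ties frequent, which
    is where selection logic can diverge.
    """
    start = dt.datetime(2019, 5, 1) + dt.timedelta(
        hours=int(rng.integers(0, 48))
    )
    n_windows = int(rng.integers(1, 5))
    stay = ("P1", start, start + dt.timedelta(hours=float(
        rng.uniform(1, 12 * n_windows)
    )))
    nurses = [f"N{i}" for i in range(int(rng.integers(1, 7)))]
    n_events = int(rng.integers(0, 21))
    lo, hi = stay[1], stay[2]
    grid = int((hi - lo).total_seconds() // 1800) + 1
    events = [
        (
            "P1",
            nurses[int(rng.integers(len(nurses)))],
            lo + dt.timedelta(seconds=1800 * int(rng.integers(grid))),
        )
        for _ in range(n_events)
    ]
    return events, [stay]
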