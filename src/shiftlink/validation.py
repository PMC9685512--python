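"""Validation against chart-review labels: stratified sampling of patient
shifts, confusion-matrix construction, and accuracy/precision with exact
(Clopper-Pearson) binomial confidence intervals.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .records import (
    Assignment,
    Category,
    ConfusionMatrix,
    MetricEstimate,
    ReviewLabel,
)
from .shifts import PatientShiftKey


def stratified_sample(
    assignments: Sequence[Assignment],
    n_total: int,
    seed: int,
) -> list[Assignment]:
    """Draw a stratified sample matching the six category proportions.

    Per-category quotas are the largest-remainder rounding of
    ``n_total * share`` (so they sum exactly to ``n_total``); sampling is
    without replacement within each category and reproducible by seed.
    Remainder ties are broken in category order 1..6.
    """
    if n_total < 0:
        raise ValueError("n_total must be nonnegative")
    by_category: dict[Category, list[Assignment]] = {c: [] for c in Category}
    for a in assignments:
        by_category[a.category].append(a)
    total = len(assignments)
    if total == 0:
        raise ValueError("no assignments to sample from")
    quotas = allocate_quotas(
        [len(by_category[c]) for c in Category], n_total
    )
    rng = np.random.default_rng(seed)
    sample: list[Assignment] = []
    for category, quota in zip(Category, quotas):
        pool = sorted(by_category[category], key=lambda a: (a.patient_id,
                                                            a.shift))
        if quota > len(pool):
            raise ValueError(
                f"category {int(category)} has only {len(pool)} shifts "
                f"but a quota of {quota}"
            )
        picks = rng.choice(len(pool), size=quota, replace=False)
        sample.extend(pool[i] for i in sorted(picks))
    return sample


def allocate_quotas(counts: Sequence[int], n_total: int) -> list[int]:
    """Largest-remainder apportionment of ``n_total`` across strata."""
    total = sum(counts)
    if total == 0:
        raise ValueError("cannot allocate quotas over empty strata")
    exact = [n_total * c / total for c in counts]
    base = [int(np.floor(q)) for q in exact]
    shortfall = n_total - sum(base)
    remainders = sorted(
        range(len(counts)),
        key=lambda i: (-(exact[i] - base[i]), i),
    )
    for i in remainders[:shortfall]:
        base[i] += 1
    return base


def confusion(
    assignments: Iterable[Assignment] | Mapping[PatientShiftKey, Assignment],
    review_labels: Iterable[ReviewLabel],
) -> ConfusionMatrix:
    """Tally algorithm calls against chart-review labels.

    TP: algorithm named a nurse and review names the same nurse.
    FP: algorithm named a nurse; review names a different nurse or none.
    FN: algorithm named none; review names a nurse.
    TN: both name none.
    """
    if not isinstance(assignments, Mapping):
        assignments = {a.key: a for a in assignments}
    tp = fp = fn = tn = 0
    for label in review_labels:
        try:
            called = assignments[label.key].primary_nurse_id
        except KeyError:
            raise KeyError(
                f"review label for unknown patient shift {label.key}"
            ) from None
        truth = label.reviewed_nurse_id
        if called is not None:
            if truth == called:
                tp += 1
            else:
                fp += 1
        else:
            if truth is not None:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def clopper_pearson(successes: int, n: int,
                    alpha: float = 0.05) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval.

    Computed from beta-distribution quantiles, the closed form of inverting
    the binomial tail probabilities.  The lower bound is exactly 0 when
    ``successes == 0`` and the upper bound exactly 1 when
    ``successes == n``.
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    low = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2, successes, n - successes + 1)
    )
    high = 1.0 if successes == n else float(
        sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    )
    return low, high


def accuracy(cm: ConfusionMatrix, alpha: float = 0.05) -> MetricEstimate:
    """(TP + TN) / N with its exact binomial interval."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    correct = cm.tp + cm.tn
    low, high = clopper_pearson(correct, cm.n, alpha)
    return MetricEstimate(point=correct / cm.n, ci_low=low, ci_high=high,
                          n=cm.n)


def precision(cm: ConfusionMatrix, alpha: float = 0.05) -> MetricEstimate:
    """TP / (TP + FP) with its exact binomial interval."""
    called = cm.tp + cm.fp
    if called == 0:
        raise ValueError("algorithm made no positive calls; "
                         "precision is undefined")
    low, high = clopper_pearson(cm.tp, called, alpha)
    return MetricEstimate(point=cm.tp / called, ci_low=low, ci_high=high,
                          n=called)
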