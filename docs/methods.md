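# Methods

## Problem and model

Bedside ICU nurses leave timestamped electronic signatures when they
document clinical assessments or administer medications. Binning those
signatures into 12-hour nursing shifts and asking *who charted most, for
longest* identifies the primary nurse for each patient shift. The model
rests on two behavioral assumptions: the primary nurse charts more often
on their patient than any other nurse during the shift, and their charting
spans more of the shift than that of nurses who document briefly
(cross-coverage during breaks, emergencies, or hand-offs).

### Shift geometry

Wall-clock time is tiled by half-open 12-hour windows anchored at 07:00
and 19:00; the night shift is labeled by its start date, so 00:00–06:59:59
belongs to the previous date's night shift. All timestamps are naive local
wall-clock datetimes at second resolution. "Until 6:59:59 PM" and the
half-open bound `[07:00, 19:00)` coincide at second resolution; the
half-open form is also unambiguous at finer resolutions. Because windows
are defined by wall-clock boundaries, the night shift spanning a daylight
saving transition covers 11 or 13 elapsed hours; this is documented
behavior, not corrected.

A patient shift exists for every window overlapping a patient's ICU stay
interval `[icu_in, icu_out)`. Overlapping stay records for one patient are
retained with a warning and their windows unioned (discarding data is
worse than double-listing a window that enumeration dedupes). Events are
**not** clipped to the stay interval: any signature inside an existing
patient shift's window counts, even if stamped before admission or after
discharge within that window — transition-period charting (ward or
operating-room nurses, discharge documentation) is deliberately visible to
the algorithm, since hiding it would silently change the selection
problem. Events falling in windows where the patient has no shift at all
are reported as unattached.

### Selection

Per (patient shift, nurse), the inputs are the count of unique charting
seconds and the first-to-last charting interval. Step 1 takes the argmax
by count, breaking ties by the longest interval; a tie on both means no
primary nurse — the procedure refuses to guess rather than introduce
randomness. Step 2 re-runs step 1 with the *step-1* primary of the
immediately preceding contiguous shift removed from the candidate set.
Two deliberate readings of that rule:

* **Step-1, not chained step-2, prior results.** With one nurse charting
  across three consecutive windows, the middle and last windows are both
  voided: the exclusion of shift *k* always consults the step-1 result of
  shift *k−1*, even when step 2 voided shift *k−1* itself.
* **Contiguity.** After a gap in the patient's shift sequence (ICU
  discharge and readmission), no exclusion applies: the late-charting
  mechanism the rule guards against is only plausible across adjacent
  windows.

Interval comparisons are at second resolution; equal durations are a true
tie. The whole pipeline is a pure function of (events, stays): invariant
to row order and duplicated rows.

### Categories

Each patient shift receives exactly one of six outcome categories.
Categories 1–3 and 5 describe the decisive comparison over the
*post-exclusion* candidate set (1 = one candidate remained, 2 = unique
count maximum, 3 = tie broken by interval, 5 = unbreakable tie);
4 = nobody charted; 6 = the only charter was the excluded prior primary.
This makes category 6 well-defined and keeps 1–3 descriptive of the
comparison that actually decided the shift. Categories 1–3 coincide
exactly with shifts carrying a named nurse, and the six counts partition
the enumerated patient shifts.

## Validation machinery

Chart-review labels (one per reviewed patient shift, naming a nurse or
explicitly "none") are compared to algorithm output as: TP — same nurse;
FP — algorithm named a nurse, review names a different one or none;
FN — algorithm named none, review names a nurse; TN — both none.
Accuracy = (TP+TN)/N; precision = TP/(TP+FP). Both carry exact
Clopper–Pearson 95% intervals computed from beta-distribution quantiles,
the closed form of inverting the binomial tail sums; the test suite
cross-checks them against a direct tail-sum bisection to 1e-9 for all
n ≤ 500. Review sampling is stratified by category with largest-remainder
rounding of `n_total × share` (the rounding rule is a package choice; ties
in remainders break in category order) and is reproducible by seed.

## Synthetic data generator

The simulator emulates the three input tables with known ground truth. Per
patient: one ICU stay in one unit, admission uniform over a 30-day
horizon, length of stay log-normal in hours (`los_log_mean = 3.87`,
`los_log_sigma = 1.0`: median ≈ 48 h, a long right tail, and partial
boundary windows at every stay edge). Per patient shift: a scheduled
primary nurse drawn from the unit roster, never repeating the adjacent
prior shift's primary (mirroring 12-hour scheduling; rosters below two
nurses are rejected). The primary's charting is one guaranteed
start-of-care signature plus Poisson streams at 2 assessments/h and 0.5
medication administrations/h over the window ∩ stay intersection. Defaults
for the charting rates are stated assumptions about plausible ICU
documentation density, not estimates from data.

Contamination scenarios, each tagged in the truth table:

* `cross_coverage` (p = 0.15): another nurse charts `k ~ Poisson(2)` times
  inside a ≤30-minute span — low count *and* short interval, so both
  selection inputs separate them from the primary;
* `late_charting` (p = 0.10): the outgoing primary charts
  `m ~ Poisson(3)` times in the first hour of the patient's next shift —
  the exact mechanism the prior-shift exclusion neutralizes;
* `orientee` (p = 0.02): a trainee co-signs at exactly the primary's
  charting times, producing an unbreakable tie (truth still names the
  primary, so these shifts are unrecoverable by construction);
* `no_documentation` (p = 0.5 *given* an in-ICU overlap under 2 h): a
  short boundary shift leaves no signatures; truth records "none".

All draws go through counter-based substreams keyed by (seed, patient,
window index), so output is byte-reproducible and independent of
generation order. With all contamination probabilities zero, the scheduled
primary is the unique charter of every documented shift and the adjacent
no-repeat scheduling makes the exclusion a no-op, so recovery is exactly
100% — this is a construction guarantee, verified over five seeds at
~1,100 patient shifts each.

What the simulator does *not* model: multiple ICU stays per patient,
irregular (non-12-h) nurse schedules, float/agency staffing, charting-rate
heterogeneity across nurses, or real EHR quirks such as clock skew and
bulk-import timestamps. Perfect clean-configuration recovery therefore
demonstrates correctness of the selection logic, not expected performance
on real extracts; the contaminated scenarios probe the documented failure
modes one at a time, and their default frequencies are round, plausible
choices rather than calibrated estimates.

## Numerical and interface choices

* CSV, UTF-8, header row, ISO 8601 timestamps; a fixed dialect keeps
  round-trips bit-exact. Empty nurse fields are the none-marker.
* Reading is loss-free and order-preserving; duplicate event rows are
  retained at read time because deduplication is an algorithm step.
* Assessment and medication signatures are pooled with equal weight; the
  two sources are distinguished in the schema but not in selection.
* Problem sizes in the test suite (≈1,100-shift simulations, 500-fixture
  oracle sweeps, n ≤ 500 interval grids) were chosen so the full suite
  runs in well under a minute while still exercising every branch of the
  selection rule.
* Exit codes: 0 success, 2 input/schema error (with file and line), 3
  internal invariant breach. Every run logs per-stage row counts and
  writes a JSON manifest (inputs, seed, version, counts) — at
  multi-million-event scale, count auditing is the primary debugging tool.

## Known limitations

* The inference target is a *single* primary nurse per patient shift;
  team-based or split assignments are out of scope, and the orientee
  scenario shows the deterministic rule correctly abstains rather than
  resolves them.
* Only assessment and medication signatures are modeled; other charting
  domains (pain reassessments, transfer forms) are invisible, which in
  real data is a documented source of algorithm-vs-review disagreement.
* Shift anchors are fixed at 07:00/19:00; sites with different shift
  grids would need a code change, not a config flag.
* Accuracy/precision are the only review metrics exposed; recall and NPV
  are derivable from the confusion matrix but intentionally not reported.
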