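# Methods

## Coordinate conventions

All temporal reasoning is done on half-open integer-day intervals
[start, end), with day indices counted from 1970-01-01. A dispensation
picked up on day *d* with *s* days supply covers [d, d + s). Under this
convention two back-to-back supplies (*x* ends exactly where *y* starts)
share no covered day and leave no gap — the *meets* relation — and at
day granularity every ordered pair of non-degenerate intervals falls
into exactly one of the 13 Allen relations; the test suite verifies this
exhaustively over a small endpoint grid. Source data are date-resolved,
so time of day is discarded. The choice of an exclusive end is a
documented convention of this package, not a property of the source
fields.

## The episode state machine

Records of one person are sorted by (coverage start, drug class,
coverage end) and swept once. The machine keeps one *thread* per drug
class currently contributing coverage; each thread carries its records
and its coverage end (the maximum post-shift end among them).

Same-drug links follow the four manipulation rules: concatenation
(*meets*), permissible gap (*before* with gap ≤ G_d continues, > G_d
discontinues), temporal margin (an overlap of ≤ ε₁ days shifts the later
record forward to abut the thread and reclassifies the pair as *meets*;
longer overlaps are left untouched), and aggregation (nested relations —
*starts*, *finishes*, *contains*, *equals* — merge into piecewise dose
segments, with daily doses summed over the shared period; total
dispensed mg is conserved).

Cross-drug links compare the new record against the active thread with
the latest coverage end. With a positive gap, the *previous* drug's
permissible gap serves as the grace period: within it the link is a
transition (a switch event); beyond it a new episode begins. With
overlapping coverage: a co-dispensation of ≤ ε₂ days recodes the overlap
to *meets* and logs a switch; a longer one opens a concurrent thread
with no adjustment. Short nested cross-drug records (co-dispensation
≤ ε₂ in *contains*/*starts*/*finishes* form) are absorbed into the
encompassing drug — they contribute coverage and dose but no separate
drug to the episode — while short *equals* pairs are excluded outright:
both records are dropped and flagged, since keeping either side would
require choosing a survivor on no evidence. Longer nested and *equals*
co-dispensations open concurrent threads.

An episode closes when, at the next record (or end of data), every
active thread's coverage end has been exceeded by more than its drug's
permissible gap; each thread carries its own gap clock, which reduces to
"the gap of the last medication dispensed" in the single-thread case.
Typing: monotherapy iff one drug class remains after absorption;
otherwise *has_multi* := longest co-dispensation segment > ε₂ and
*has_switch* := at least one switch event decide transition (switch
only), multitherapy (concurrency only), or transition-multitherapy
(both).

Two generalizations beyond the pairwise rules were needed for
consistency. First, link decisions measure gaps and overlaps against the
thread's coverage end rather than the last record's end; nested records
can leave coverage beyond the last record, and the coverage end is what
the close rule watches. Second, cascading early-refill shifts can leave
the next raw record entirely behind its shifted predecessor
(*overlapped_by*/*during* instead of *overlaps*); this is the same
stockpiling pattern and is recoded the same way — shifted forward to the
coverage end when the coverage overlap is within ε₁. On plain two-record
inputs both reduce exactly to the pairwise rules.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| ε₁ (`epsilon_same`) | 7 | days | largest same-drug overlap treated as an early refill |
| ε₂ (`epsilon_cross`) | 14 | days | largest cross-drug co-dispensation treated as a switch |
| G_methadone, G_srom | 5 | days | permissible gap, full agonists |
| G_bup_nal | 6 | days | permissible gap, partial agonist |
| G_ioat | 3 | days | permissible gap, injectable OAT |

The gaps reflect BC clinical guidance and the drugs' half-lives; the
margins separate routine early refills (bounded by the province's
refill-too-soon policy of ≤ 14 days of remaining supply) from clinically
meaningful overlaps. `margin_sensitivity` reports the date-shift
statistics (mean, SD, median, mode, max per drug) of the recoding
cascade under candidate margins, including the no-margin scenario in
which every overlap is recoded; the mean shift is non-decreasing in the
margin.

## Cleaning

Three deterministic rules run in a fixed order — consolidate split
doses, repair QPD (quantity-per-day) outliers, cap days-supply overruns
— because capping depends on consolidated dates and QPD repair should
see original supplies. All three compare records within one
(person, product-code) stream. Granularity matters: same-day or
overlapping records of *different* products of one drug class are
legitimate dispensing (witnessed ingestion, split dosing, early refills
of a different formulation) and are left to the episode builder's
temporal-relation machinery; collapsing or capping them at drug-class
level would erase exactly the *equals* and *overlaps* relations the
framework is built to classify.

Numerical choices: the QPD reference is the median of up to two records
on each side (lower of the two middle values on even counts — the
conservative tie-break that avoids inflating the reference dose),
computed from the values as they stood at the start of the pass; a row
deviating by more than a factor of 2 in either direction is repaired,
first by recalculating the days supply (accepted only if it lies in the
plausible 1–28-day range — OAT is dispensed daily to roughly monthly —
and does not overshoot the next fill of the same product), otherwise by
resetting the quantity to the reference QPD. Rows with fewer than two
neighbours are never altered. Because corrections can interact when one
record carries several errors, the pipeline iterates to a fixed point
(in practice one extra pass), making cleaning idempotent by
construction. Free-form service-date editing is deliberately out of
scope: it risks silently fabricating data, and the days-supply cap
already enforces date/supply consistency.

## Hospital bridging

Community-pharmacy claims omit inpatient dispensations, so therapy is
assumed to continue when an admission falls inside an ongoing episode.
Implemented rule set: (a) an admission inside the episode span, or
inside the closing drug's permissible gap after its coverage end,
bridges the episode; (b) the gap clock restarts at discharge, so a
dispensation of any OAT drug within that gap after discharge merges the
would-be-separate episodes, adding the stay length to
`bridged_hospital_days`; (c) a drug change across the stay counts as a
switch. Each is a documented package choice, toggleable via
`bridge_hospitalizations`. Hospitalized days count toward episode
duration; the bridged-day field lets either convention be recovered.

## Synthetic cohorts

The generator samples per-record relation categories (not-applicable +
the seven base relations) from per-drug mixtures and realizes intervals
satisfying each drawn relation. Default mixtures are calibrated to the
relation mix characteristic of BC OAT dispensing: *before* dominant for
methadone (~99.4%) and iOAT (~96.9%), *equals* common for
buprenorphine/naloxone (~21.5%) and SROM (~20.9%) through same-day
witnessed/split dosing. Realization is the inverse of classification,
and the round-trip `classify(prev, realize(label, prev)) == label` holds
for all 13 labels. In a sorted stream the later record can never start
first, so the *finishes* category is realized in its sorted-feasible
orientation and frequency reports collapse inverse labels onto base
names.

Whole-cohort generation additionally tracks episode-level ground truth
(boundaries, type, switch count) by simple coverage-end arithmetic on
the drawn quantities at generation time; the episode builder recovers it
exactly on uncorrupted output. Cross-drug co-dispensation tails emulate
the two dominant empirical sequences — a short return overlap
(iOAT+SROM, durations ~1–7 days) and a longer switch overlap
(SROM→methadone, ~3–30 days). Error injection plants split-dose rows
(recovered exactly by consolidation), QPD outliers (×8 quantity,
detectable against uncorrupted neighbours), and supply overruns (supply
and quantity scaled together so only the cap rule can catch them), each
recorded in a ledger.

What the generator does not emulate: calendar-time policy shifts,
person-level covariates, dose tapering, informative censoring, and
pharmacy-level idiosyncrasies. Days supply is floored at 3 days so that
every relation is constructible against any record (*contains* needs an
enclosing interval of ≥ 3 days); real iOAT is typically dispensed daily.
Per-person daily dose is held constant (realistic for maintenance
therapy, and what makes QPD repair well-posed). Passing tests on this
material therefore demonstrates the correctness of the construction
rules under controlled temporal structure, not performance on the full
messiness of production claims.

## Reporting

Quartiles use the median-of-halves (Tukey hinge) rule — the halves
include the overall median when the count is odd — stated here because
quantile conventions differ across software. Co-dispensation patterns
are maximal spans where at least two drugs' raw (pre-recode) coverage
overlaps, labelled by which drug continues afterwards:
`A->(A+B)->A` (return), `A->(A+B)->B` (switch), or `other`.

## Problem sizes

The test suite exercises exhaustive relation classification over all
interval pairs with endpoints in 0..6, boundary scans over gaps 0–10 and
overlaps 1–30 days, generated cohorts of 25–200 persons, and
mixture-recovery streams of 100,000 records (accepted within 3 binomial
standard errors); `scripts/acceptance.py` uses the same sizes. The full
suite runs in a few seconds on one CPU.

## Known limitations

Cleaning thresholds (deviation factor 2, ±2-record window, 1–28-day
plausible supply) are package defaults with documented rationale, not
values estimated from data. Cross-drug links always compare against the
most recently active thread; with three or more simultaneously active
drugs the choice of reference thread is a tie-break (latest coverage
end, then drug name). Whether a long same-drug overlap should contribute
summed dose or only extend coverage is ambiguous; both records are
retained and dose segments are summed, which conserves dispensed mg.
Transition washout days (within-gap *before*) are included in episode
duration.
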