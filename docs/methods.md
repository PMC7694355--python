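# Methods

## Problem setting

ED presentations and admitted hospital episodes live in separate
administrative databases keyed only by a person-level identifier. An
admitted episode that *stemmed from* an ED visit must be inferred from
timestamps. For frequent presenters — people with many contacts, often
several on one day — calendar-date matching is ambiguous, so the method
operates on minute-resolution datetimes assembled from the separate
date and time columns administrative extracts deliver.

Timestamps are timezone-naive wall-clock values (administrative systems
record local clock time; no DST arithmetic is attempted) truncated to
the minute, the resolution at which these systems record.

## The linkage rule set

For each person every (visit, episode) combination is a candidate. A
candidate is classified against six temporal criteria over ED arrival
`A`, ED departure `D`, admission `H` and separation `S`, checked in the
precedence order **L1, L2, L4, L3, L5, L6** with first-match-wins:

* L1: `H = A`; L2: `H = D` (equalities are claimed only by L1/L2);
* L4: `A < H` and `S < D` — the whole admitted episode nested strictly
  inside the ED stay;
* L3: `A < H < D` — admission strictly inside the stay, separation at
  or after ED departure;
* L5: `0 < H − D ≤` post-departure window (default 24 h, inclusive);
* L6: `0 < A − H ≤` pre-arrival window (default 24 h, inclusive),
  additionally requiring `A < S` so the ED visit overlaps the episode.

Placing L4 before L3 and giving equalities to L1/L2 makes the six
categories a partition: every quadruple receives at most one label.
The order is configurable (`category_precedence`) for sensitivity
analysis.

Classified candidates are pruned to a one-to-one matching: sort by
(`|H − A|`, visit id, episode id) and accept greedily while both
endpoints are free. The id tie-break is a design choice — the matching
rule itself says nothing about ties — made so identical inputs always
produce byte-identical output. The greedy rule is deliberately *not*
replaced by an optimal assignment: shortest-absolute-difference-first
is the field's stated procedure, and the test suite pins the greedy
output to an exhaustive re-implementation on small instances.

Window widths trade sensitivity for specificity: wider windows can only
add classifiable candidates (a tested monotonicity property), but the
added long-lag links are the ones most likely to be unrelated
encounters. `window_sensitivity` re-runs the linkage over a grid of
widths to expose this trade-off; clinical review of long-lag links is
out of scope here.

## Continuous episodes of care

One hospital stay generates several episode records when care type or
campus changes before final discharge. Episodes are chained per person
in (admission, separation, id) order: an episode continues the open
chain iff the predecessor's separation mode is a planned-transfer code
(statistical separation, transfer to another hospital) *and* its
admission falls within the chain window (default 24 h) of the anchor
timestamp. Requiring the planned-transfer code keeps unplanned
re-presentations within 24 h out of chains.

The anchor defaults to the predecessor's *separation* time: statistical
separations are instantaneous care-type changes and inter-hospital
transfers depart from the end of the previous episode. Anchoring on the
predecessor's admission is available as a config option since the
24-hour phrase is ambiguous between the two readings. Episodes that
overlap their predecessor within a chain are permitted (same-hospital
statistical separations can share timestamps) but reported. A
transfer-coded episode with no successor inside the window stays a
chain terminus and is counted as a dangling transfer in the chaining
report.

By default linking runs after chaining and continuation episodes are
ineligible link targets, so an ED visit links to the index admission of
the stay it produced. Setting `link_after_chaining=False` reproduces a
flat two-table join in which continuations may capture visits.

## Cleaning

Rules run in declared order and each flags, repairs or drops:

* missing clock time: impute 00:00 and flag (default), or drop under
  the `drop` policy — imputation keeps the record available to the
  join while marking its uncertainty;
* midnight date slip: end < start with `end + 24 h` giving a duration
  in (0, 24 h] → end advanced one day, flagged as modified. This is the
  signature of an encounter spanning midnight recorded with both
  timestamps on the same date;
* still end < start: dropped under `strict` (default), retained with a
  flag under `lenient`.

The cleaning report itemises every action per record id; counts satisfy
`n_input = retained + dropped` and `n_flagged ≥ n_modified + n_dropped`.

## Disposition-code audit

Two 2×2 cross-tabs compare code-based expectation against links found:
ED departure-status groups (admission expected: ward, procedure room,
transfer to another campus; no admission: usual residence, left before
completion, died in ED) over visits, and admission-type groups (the
single "emergency via this hospital's ED" code versus the non-specific
remainder) over all episode records. Unmapped codes are excluded from
the cells and itemised, since code groupings drift across collection
years — the groups are a YAML-editable mapping, not constants.
Percentages are rounded half-up to integer percent; nonzero shares
under 0.5% render as `<1%`, matching administrative reporting style.

## Synthetic cohort generator

The generator emulates de-identified extracts for an urban cohort of
people who inject drugs observed January 2008 – June 2013. Defaults are
fixed at the reference cohort's scale and are not tuning knobs: 688
participants; negative-binomial visit counts with mean 5.03 and
dispersion 0.8 (heavy tail — exact utilisation rates for such cohorts
are unpublished, so dispersion is an explicit config field); admission
probability 1190/3459 per visit; the published per-category link mix
(206, 7, 801, 21, 43, 112)/1190; chain lengths (1654, 94, 6, 3, 1)/1758;
568 direct admissions with no ED visit; L5 lags with 70% mass within
2 h; L6 offsets with 90% mass within 11 min; misclassification rates
given as (admitted-side, non-admitted-side) pairs — (377/1190, 59/2269)
for departure status and (94/1190, 79/687) for admission type — because
the published cross-tabs imply asymmetric error rates that one scalar
cannot express; midnight-slip probability 0.004 (~20 errors per ~5000
records).

Construction is inverse to the classifier: each admitted visit draws a
category and receives an episode whose `H`/`S` are built to satisfy
that category's definition exactly, which is the module's core tested
invariant. Each person's encounter events are placed in distinct
21-day slots so no cross-event candidate is classifiable; same-day
multiple presentations occur *within* a slot among non-admitted visits.
Consequently, with midnight errors disabled (or after cleaning repairs
them), running chain + link on generated data recovers the planted
truth with precision = recall = 1 for any seed — a property test, not a
benchmark.

What the generator does **not** model: clinical diagnoses and their
correlation with admission, seasonal or diurnal arrival patterns,
cross-event ambiguity (two genuinely close unrelated encounters), or
realistic identifier quality. A green recovery test therefore
establishes the algorithms' correctness on well-separated encounters,
not linkage accuracy on real data, where closely spaced unrelated
records can produce false matches within the 24-hour windows.

Episode lengths of stay are log-normal (ED median 3 h, hospital median
2 days) truncated so one event fits its slot; only their interaction
with category construction matters for testing.

## Numerical and degenerate-input choices

* Minute resolution throughout; seconds truncated on ingestion.
* Both link windows inclusive (`≤ 1440` minutes).
* Percent rounding: decimal half-up, not banker's rounding.
* Empty candidate sets, zero-link cohorts and all-zero cross-tabs are
  legal: proportions become `None`/`n/a` rather than raising.
* Cross-tab agreement proportions are undefined (reported unavailable)
  when their denominator is empty.
* The category-census and stay-population fixtures are synthetic
  constructions realising published marginal counts; they are built at
  run time by `planted_category_pairs` / `planted_stay_population`.

## Known limitations

* The greedy matching is order-dependent by design; a minimum-weight
  assignment could differ on dense same-day clusters.
* Chaining trusts separation-mode codes; planned transfers with
  miscoded separations are not recovered from campus or diagnosis
  similarity.
* The audit quantifies code/link agreement only; it does not attempt
  statistical testing or clinical plausibility scoring of long-lag
  links.
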