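# Methods

`coprescribe` measures concurrent prescribing of opioids (for non-cancer
pain) and antidepressants in primary-care electronic health records shaped
like a CPRD GOLD extract. This note records the model, the conventions the
implementation commits to where the underlying design was open, and what
the synthetic validation does and does not demonstrate.

## Cohort model

Adults aged 18–100 are observed over a fixed study window (default
2010-01-01 to 2019-12-31). Entry is the latest of: one year after
registration, one year after the practice's up-to-standard date, 1 January
of the year the person turns 18, and the window start. Exit is the earliest
of death, transfer out, the practice's last data collection, 1 January of
the year the person turns 101, and the window end; same-day ties resolve by
the fixed precedence death > transfer_out > last_collection > turned_101 >
study_end. Follow-up is a closed interval `[entry, exit]` contributing
`exit − entry + 1` days, so a one-day record contributes one day.

A first record of cancer, terminal illness, heart failure or opioid misuse
**excludes** the person when dated strictly before entry and **censors**
follow-up at its date otherwise. Conventions at the boundaries: an event
dated exactly on entry censors at entry (one day of follow-up) rather than
excluding; an event on the exit date replaces the administrative exit
reason unless the exit was a death. "One year after" means the calendar
anniversary, with 29 February mapping to 1 March. Persons whose entry
exceeds their exit have no eligible follow-up and are dropped (tallied
separately from exclusions). There is no re-entry: one follow-up interval
per person.

## Duration estimation and drug eras

Prescription end dates are estimated from quantity and daily dose, the
standard drug-era construction for UK primary-care data. The rule chain
per script:

1. `days = round(quantity / daily_dose)`, floored at 1, when the daily
   dose is recorded;
2. otherwise the stated duration, if recorded;
3. otherwise the median of valid computed durations for the same drug
   (`fallback_strategy="drug_median"`, the default);
4. otherwise a global default (28 days, the typical UK repeat script).

Any result above the cap (183 days ≈ a six-month supply) is capped and its
provenance recorded as `capped`. The published descriptions of this
algorithm family leave several decision points open; every constant here
lives in `DurationConfig` and every estimate carries a `duration_source`
tag whose distribution is reported in the run summary. An optional
`implausible_factor` routes extreme quantity/dose results to the fallback
chain instead of the cap; it is off by default so that the cap, not the
fallback, governs outliers.

Same-drug intervals for one person are merged into coverage spans by
union, joining two intervals when the uncovered gap between them is at most
`same_drug_gap_days` (default 0: only overlap or exact adjacency joins).
There is **no stockpiling**: an early refill never pushes coverage beyond
the union of the scripts' own intervals. For an overlap-defined outcome
this is the conservative choice — queueing surplus supply forward would
manufacture co-prescription days.

## Outcome

Co-prescribing is an opioid coverage span and an antidepressant coverage
span sharing at least one day inside follow-up. Spans are clipped to
`[entry, exit]` *before* intersection, so censoring shortens or removes
overlap deterministically. Two granularities are kept, because the
questions differ:

* **events** — one per (opioid drug × antidepressant drug × maximal
  intersection interval); the unit for combination counts, contraindication
  flags and the headline median overlap length;
* **episodes** — per-person maximal unions of event intervals; the unit
  for person-level duration statements ("lasted ≥ 365 days").

The median/IQR overlap length is computed over pairwise events by default;
`PipelineConfig(episode_level_lengths=True)` switches to episodes.
Contraindicated pairs are a membership test against the interaction
codelist, validated at load time (each member must carry the right class).
Sensitivity thresholds (≥ 14, 28, 365 days of overlap) are a filter that is
antitone in the threshold by construction.

## Rates

Follow-up is split into calendar-year person-time cells; person-years are
days / 365.25. Stratum labels are sex, deprivation quintile (person-level
Townsend, practice-level fallback), ethnic group (primary-care record,
hospital-record supplement, else "not known") and the age band attained on
1 January of the cell year (`year − birth_year`, all the birth date the
data model carries). Descriptive tables use the entry-year age band;
per-year rates use attained age — a decade of frozen entry age would
distort the age-specific curves.

* **Prevalence**: numerator = distinct persons with ≥ 1 co-prescribed day
  in the (year, stratum) cell; denominator = full follow-up person-years in
  the cell (not truncated at events). Period-wide rates count a person once
  per prevalent calendar year, making the overall rate the person-year-
  weighted mean of the yearly rates — the only convention under which
  per-year curves and an overall rate are commensurable.
* **Incidence**: persons with any opioid/antidepressant overlap before
  entry (full lookback over supplied prescriptions, which the generator
  emits from 2008) are removed from numerator and denominator; the rest
  contribute at-risk time from entry to the earlier of first event and
  exit, with the event day itself at risk (a first event on the entry date
  contributes one day and one event).

Confidence intervals are exact Poisson (gamma-quantile) limits scaled by
1000/person-years — correct in small strata, indistinguishable from the
normal approximation in large ones.

## Incident-event descriptors

Ordering compares the earliest issue date of each class among prescriptions
on or before the first event date, using all supplied history including
pre-entry records (consistent with the incidence lookback); equal dates are
`same_day`. "Long-term opioid use" requires the first opioid issue ≥ 365
days before the first co-prescription **and** no uncovered gap longer than
`max_gap_days` (default 90) between consecutive opioid spans up to the
event — a pure first-issue reading would call one script from two years
earlier "long-term". Indication flags (depression, anxiety/phobias,
neuropathic pain) are true when a mapped clinical event is dated on or
before the first co-prescription, the boundary day inclusive.

## Synthetic data generator

The licensed source extract cannot be shipped, so the generator emits the
five input tables with a planted ground truth. It emulates: the seven-band
age mix, a five-group ethnicity distribution with two-stage missingness
(≈41% missing in the primary-care record, ≈54% of those recovered from the
hospital table, leaving ≈19% unknown), person-level deprivation with a 30%
missing fraction, practices with early and late data-quality windows, and
episode-structured prescribing — an initiation process per class, repeat
scripts drawn from the {7, 14, 28, 56, 84}-day mixture with a continuation
probability and a ±5-day renewal jitter that produces the overlap/gap
structure a drug-era estimator must handle. Co-prescribing arises from a
propensity multiplier (default 4.5) on the opioid initiation hazard while
antidepressant coverage is active, via thinning of a bounded-rate process.
Quantity ≡ daily dose × true days for every script; 5% of scripts have the
dose blanked (half of those carry a stated duration) to exercise the
fallback chain. Default initiation rates (0.22 opioid, 0.16 antidepressant
episodes per person-year) were calibrated once against the generator's own
ground truth so the cohort's overall prevalence lands in the tens per 1000
person-years, then frozen; they are study conditions, not tuning knobs.

Ground truth is computed by a brute-force day-enumeration reference
(`coprescribe.oracle`) that marks each calendar day per person on a boolean
grid — independent of the interval arithmetic under test. The generator is
deterministic: identical parameters and seed give byte-identical tables.

What the generator does **not** emulate: the joint demographic distribution
of real UK practices (only marginal mixes), regional composition,
dose-strength (mg/MME) information, secondary-care prescribing,
non-adherence and unfilled scripts, or terminology noise (the codelist CSVs
are the terminology boundary). Passing tests therefore demonstrate
correctness of the *computation* — eligibility, duration, overlap, rates —
under realistic structure, not fidelity of any particular rate to the
licensed data.

## Validation design and problem sizes

* Exact equivalence: 50 cohorts of 200 patients against the
  day-enumeration reference, exact equality of follow-up, co-day sets,
  pair event counts, prevalent/incident persons per year.
* Parameter recovery: 10 cohorts of 5,000 patients; estimated per-year
  prevalence and incidence within 3 Monte-Carlo standard errors of the
  planted truth (the residual bias source is the drug-median fallback on
  the ~2.5% of scripts with neither dose nor stated duration).
* Conservation identities, planted-censor checks and byte-level
  determinism on cohorts of 200–2,000.
* CI calibration: 1,000 simulated Poisson counts at a fixed true rate;
  empirical coverage within 95% ± 2%.
* The acceptance script reports headline quantities from a 20,000-patient
  "typical" cohort.

These sizes were chosen as the smallest at which the stochastic checks are
stable; all are configurable upward.

## Known limitations

* Age is carried as birth year only (the source data model's granularity),
  so "attained age on 1 January" is `year − birth_year`.
* The overall prevalence numerator convention (once per prevalent year) is
  an interpretation; a strict distinct-person overall numerator is
  recoverable from the events table.
* The per-combination event unit is the maximal pairwise overlap interval;
  counting prescriptions issued during overlap would give larger numbers.
* No dose modelling, no adverse-event outcomes, no age standardisation or
  regression — the analysis reports crude stratified rates by design.
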