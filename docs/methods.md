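# Methods

## Scope and data model

`pdckit` implements a claims-based longitudinal adherence analysis for
drug-class dispensing streams.  The inputs are two flat tables: participants
(demographics, diabetes flag, death date, withdrawal flag) and dispensings
(participant, date of supply, ATC code, pharmacy item code).  All analysis
parameters — calendar anchors, gap rule, adherence threshold, per-class
standard coverage days (SCD) — are configuration (`StudyWindow`,
`ClassConfig`), with defaults matching an Australian PBS study of
glucose-lowering medications: capture from 1 Jul 2012 (PBS under-captured
subsidised items before then), baseline window 1 Jul–31 Dec 2012, analysis
window 1 Jan 2013–31 Dec 2019.

## Drug-class mapping

Single-agent products resolve by longest ATC-prefix match (metformin
`A10BA02`, sulfonylureas `A10BB`, TZD `A10BG`, DPP4i `A10BH`, GLP1RA
`A10BJ`, SGLT2i `A10BK`, insulin `A10A`, acarbose `A10BF01`).  Fixed-dose
combinations (`A10BD`) count as one dispensing of *each* analysed
constituent, using the constituent class's SCD; combinations whose second
agent is not an analysed class (e.g. metformin–repaglinide, `A10BD14`) are
treated as unmapped rather than silently reduced to a single class.  Before
2017 both GLP1RA and SGLT2i products were coded `A10BX`; these resolve by
pharmacy item code through a user-overridable table.  The shipped item codes
are **synthetic placeholders** — the real PBS item lists are not public in
this form — and an `A10BX` record with no override is a hard error, because
guessing would corrupt two classes at once.  Unmapped records are excluded
and counted in the load report.  Insulin and acarbose are never given a PDC
(variable daily dosing; small user base): their records only inform the
exclusion cascade and switch detection.

## Cohort and user status

Exclusions are sequential and mutually exclusive, each participant counted
at the first failing step: withdrew → no self-reported diabetes → died
before the analysis start → only ever dispensed acarbose/insulin → no
glucose-lowering record on/after the analysis start.  This flow-diagram
accounting conserves the input total by construction, and its arithmetic is
what the designed-cohort acceptance check exercises.

Per drug class, a participant is *prevalent* with ≥1 dispensing in the
baseline window (both endpoints inclusive; a 31 Dec 2012 record qualifies),
*incident* with none in the baseline window and ≥1 after it, else a
nonuser.  Baseline records determine status only; they never enter PDC.

## Coverage model

Dates are day ordinals; coverage intervals are half-open `[start, end)`.
The default **stockpile** model treats each dispensing as SCD days of
medication added to the pill-box: coverage begins at the later of the
supply date and the end of current coverage, so early refills are banked
and never overlap, and same-day duplicate supplies each add SCD days.  The
claims literature is divided between this carry-forward convention and
discarding overlap; the alternative **union** model (each supply covers
`[supply, supply+SCD)`, overlap discarded) is available via
`coverage_model="union"` for sensitivity analysis.  Both are verified
exactly — covered-day counts, not approximately — against a brute-force
day-by-day pill-count simulation (`scripts/daygrid.py`) on randomised
instances; the oracle is deliberately kept outside the package and shares no
code with the interval engine.

## Periods, censoring and events

The index date is the first supply of the class on/after the analysis
start.  Periods are calendar anniversaries of the index (a 29 Feb index
maps to 1 Mar in non-leap years), half-open, up to five; any continuous
5-period window indexed in 2013–2014 spans exactly 1826 days.

A stream ends at the earliest of: the study end; death; or, when the class
was stopped — a same-class gap strictly greater than 365 days, either
between records (a *restart*, whose post-gap records are excluded) or from
the last record to the end of follow-up while alive — the last supply plus
SCD.  The stop is a *switch* if any other glucose-lowering class (insulin
and acarbose included) was dispensed strictly after the last supply,
otherwise a *discontinuation*.  A stop within 365 days of death is death
censoring, not discontinuation: the participant was not alive over the
would-be gap.  This also resolves the ambiguity in the switch rule's
"alive over the 12-month period" condition — aliveness over the gap is
enforced structurally, since any earlier death pre-empts the gap
classification.

Within a period, the outcome is `full` when the censor falls strictly after
the period end; a censor coinciding with the period end yields full
analysis days but the event's outcome (`died_or_study_end`, `switched`,
`discontinued`), except that administrative study-end censoring exactly at
a period boundary still counts as `full` — nothing happened *during* the
period.  Death therefore takes precedence over the period boundary on ties,
and event precedence within a period is death/study-end > switch >
discontinuation (at most one event can truncate a period under this
censoring scheme).  The censor date itself is analysable: for a
discontinuation the denominator includes the tail `last supply + SCD`, so a
partial period can include one uncovered day beyond the covered tail.

Eligibility requires two records of the class with the second within 12
months of the first (after restart exclusion this is simply ≥2 retained
records).  Exactly one record ever raises the possible-intolerance flag.
The 5-year PDC is computed over `[index, index + 5 years)` for streams whose
censor reaches the fifth anniversary.

Sensitivity analyses prescribed by the design are run by re-configuration,
not special code paths: an alternative SCD (e.g. metformin 60) via
`ClassMap.with_scd` / `--scd-override`, and the fixed-dose-combination
subgroup by passing `run_adherence(..., stream_mask=...)` so that only
combination rows form the analysed stream while switch detection still sees
all records.

## Subgroup statistics

Per class, user type and period, summaries report n, the shares included
for full vs partial analysis by reason, analysis-day and PDC moments
(mean/SD, median/IQR) and the percentage adherent; a `full_5y` row is
restricted to 5-year continuous users.  Adherence levels are
`<0.5` (strongly nonadherent), `0.5–<0.8`, `≥0.8`, boundaries closed on the
left.

Subgroup comparison is a multiple logistic regression of the adherent flag
on sex, age group in 2013 (45–54, 55–64, 65–74, ≥75; configurable),
diabetes duration group, socio-economic quintile and remoteness, fitted by
maximum likelihood with Wald 95% CIs on the log odds ratio (the default of
the major commercial packages; profile-likelihood intervals were not used).
Reference levels: male, 45–54, <10 y, quintile 1 (most disadvantaged),
major cities.  Models are fitted separately per drug class, user type and
period, with no multiplicity correction — estimates are descriptive, and
with 5 periods × several classes the user should expect some nominally
significant contrasts by chance.  An absent reference level falls back to
the modal level; complete separation drops the offending covariate; both
are recorded in the output's `note` column.

## Synthetic-data generator

The generator emulates what the pipeline consumes: per-class dated supply
streams with competing events and covariates.  Per participant-class
stream, an adherence propensity θ ∈ (0,1] is drawn once (not per refill, so
per-period PDC is stable within participant, matching the within-person
stability claims data show); inter-supply gaps are `round(SCD/θ)` days plus
uniform integer jitter of ±4 days by default.  θ comes either from a
point-mass mixture or from a two-point good/poor model
(θ_good = 0.95, θ_poor = 0.5) whose probability of "good" is logistic in
the covariates — the designed odds ratios the regression must recover.
Because θ_good maps to PDC ≈ 0.95 > 0.8 and θ_poor to ≈ 0.5 < 0.8, the
pipeline's adherent flag coincides with the good-refiller flag, which is
what makes flag-level regression-recovery studies equivalent to full
pipeline runs.

Death is participant-level (annual hazard 0.02 by default, drawn per year
from the analysis start); discontinuation and switch are per-12-month
on-treatment hazards, competing in the order death > discontinuation >
switch; a switch starts an incident stream of the destination class 14–45
days later.  Prevalent users start uniformly in the baseline window,
incident users uniformly in a configurable window (2013–2016 by default).
The default scenario scales the study's class-uptake shares to a
2,000-participant cohort.  `truth.csv` records each stream's designed
status, θ and event dates; it exists for tests and is never read by the
pipeline.

What the generator does **not** emulate: dose titration (a participant's
tablets-per-day never changes, whereas real metformin users may stretch a
box up to three times longer), item-level pack sizes and brands, seasonal
and holiday refill patterns, hospitalisation gaps, and primary
non-adherence.  Passing designed-truth recovery therefore shows the
*pipeline arithmetic* is right under the stated refill model, not that the
model captures every behaviour of real claims.

Two identifiability caveats, inherent to the rules rather than the code:
an event in the last ~12 months of follow-up cannot produce a >365-day gap
and is classified as persistence to study end; and a true discontinuer who
independently uses another class later is classified as switched (any
other-class record after the last supply triggers the switch rule).
Truth-recovery tests therefore condition on identifiable cases
(single-class scenarios, events before late 2018).

## Numerical and design choices

- Day-grid integer dates throughout; no fractional days, no time zones.
- Strict inequalities for the gap rule: a gap of exactly 365 days is
  neither a restart nor a discontinuation.
- "12 months" in the gap rule is fixed at 365 days (configurable); period
  boundaries, by contrast, are calendar anniversaries, so periods have 365
  or 366 days.
- PDC is exact rational arithmetic (integer covered days / integer analysis
  days); the adherence threshold comparison is `>=` on the float quotient,
  which is exact at the 0.8 boundary for the denominators that can produce
  it (e.g. 292/365).
- Designed-propensity recovery uses point-mass θ arms with zero jitter (so
  the arm's expected PDC is a deterministic function of the refill
  pattern).  Integer rounding of `SCD/θ` biases the realised mean PDC away
  from θ by up to |SCD/round(SCD/θ) − θ| plus an edge term — ≈ 0.008 at
  θ = 0.8 with SCD 37 — so recovery is asserted within
  max(3 Monte-Carlo SE, SCD/365), the one-script-per-year granularity bound
  fixed a priori; no dispensing-count PDC can resolve θ finer than that.
- The empty cohort is a warning with a zeroed flow, not an error; an empty
  supply stream yields no timeline; a period with zero analysis days is not
  emitted.

## Problem sizes

The shipped checks use a 267,357-row designed cohort for the exclusion
cascade, 1,000 random instances for the coverage oracle, 2,000 participants
per propensity arm, and 100/200 replicates at n = 5,000 for odds-ratio
recovery and null CI coverage — sizes chosen so the whole suite runs in
about a minute while keeping Monte-Carlo error well inside the asserted
bands.

## Known limitations

PDC measures medication on hand, not ingestion.  SCD-based coverage is
biased for dose-titrated drugs (metformin, sulfonylurea); the SCD-60 and
fixed-dose-combination sensitivity analyses mitigate but do not remove
this.  The subgroup models assume independent observations within a
class-period (one row per participant, so this holds) but periods are not
independent across the five fits.  The exclusion cascade reproduces a
specific study design; other designs (e.g. washout-based new-user designs)
would need different cohort logic.
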