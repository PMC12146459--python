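# pdckit

Long-term medication adherence from pharmacy dispensing records, measured as
the **proportion of days covered (PDC)** over successive 12-month periods.

`pdckit` is a tested, reusable pipeline for claims-based adherence studies of
the kind run on Australian PBS (Pharmaceutical Benefits Scheme) data for
glucose-lowering medications: it reads participant and dispensing tables,
maps ATC codes (including fixed-dose combinations and the ambiguous pre-2017
`A10BX` code) to analysed drug classes, applies a study exclusion cascade,
classifies prevalent vs incident users from a baseline window, builds
medication-on-hand coverage timelines with stockpiling, handles censoring by
death, study end, discontinuation and drug-class switching, and compares
adherence across socio-demographic subgroups by multiple logistic
regression.  A synthetic dispensing-record generator with known ground truth
makes every stage testable without access-restricted claims data.

## The measure

For one participant and one drug class, each dispensing contributes the
class's **standard coverage days** (SCD, the median time to re-supply; e.g.
metformin 37 days, sulfonylurea 33).  Coverage stockpiles: an early refill's
days begin when the current supply runs out.  Starting at the **index date**
(first supply on/after the analysis start, 1 Jan 2013 by default), PDC is
computed for up to five 12-month periods:

    PDC_k = (days with medication on hand in period k) / (analysis days in period k)

with **adherent** defined as PDC ≥ 0.8, and a 5-year PDC for participants
continuously on the class for all five periods (1826 analysis days for any
index in 2013–2014).  Analysis ends at the earliest of the study end
(31 Dec 2019), death, or — when a gap of more than 12 months shows the class
was stopped — the last supply plus the SCD; the stop is a **switch** when
another glucose-lowering class was dispensed after the last supply, else a
**discontinuation**.  Records reappearing after a >12-month gap are restarts
and are excluded; participants need two records within 12 months to enter
the analysis, and single-record users are flagged as possible intolerance
cases.

## Worked example

```python
from pdckit import (ClassMap, build_cohort, prepare_dispensing,
                    prepare_participants, run_adherence, worked_fixture)

participants, dispensing = worked_fixture()   # ten hand-written participants
cmap = ClassMap()                             # default ATC map and SCDs
parts = prepare_participants(participants)
resolved = prepare_dispensing(dispensing, cmap)

analysed, flow = build_cohort(parts, resolved)
print(flow.to_dict())

resolved = resolved[resolved.participant_id.isin(set(analysed.participant_id))]
periods, five_year, streams = run_adherence(resolved, analysed, cmap)
print(periods[["participant_id", "period_index", "analysis_days",
               "pdc", "adherent", "outcome"]].head(8).to_string(index=False))
```

prints

```
{'initial_total': 10, 'withdrew': 1, 'no_self_reported_diabetes': 1,
 'died_before_analysis_start': 0, 'acarbose_or_insulin_only': 1,
 'no_glm_after_analysis_start': 0, 'analysed': 7}
participant_id  period_index  analysis_days      pdc  adherent      outcome
           F01             1            365 1.000000      True         full
           F01             2            365 1.000000      True         full
           F01             3            365 1.000000      True         full
           F01             4            366 1.000000      True         full
           F01             5            365 1.000000      True         full
           F02             1            365 0.506849     False         full
           F02             2            191 0.581152     False discontinued
           F04             1            112 0.991071      True discontinued
```

Three of ten participants fall to the exclusion cascade.  F01 refills every
37 days for five full years (PDC 1.0 every period, 1826 five-year analysis
days).  F02 refills at twice the SCD — half the days covered (PDC 0.507) —
then stops: the second period is truncated at the last supply plus 37 days
with outcome `discontinued`.  F04's later records sit beyond a >12-month gap
(a restart) and are excluded, so only one truncated period remains.

## Command line

```bash
pdckit simulate --config scenario.yaml --out run/ --seed 1   # synthetic data
pdckit cohort   --participants p.csv --dispensing d.csv --out run/
pdckit pdc      --participants p.csv --dispensing d.csv \
                --scd-override metformin=60 --out run/       # sensitivity SCD
pdckit report   --participants p.csv --period-results run/period_results.csv \
                --five-year run/five_year.csv --user-status run/user_status.csv \
                --out run/
pdckit all      --out run/ --seed 1                          # whole pipeline
```

`pdckit all` writes every stage's CSV/JSON output plus a manifest with
checksums: two runs with the same seed are byte-identical.

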