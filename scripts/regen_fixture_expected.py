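"""Regenerate the worked fixture's expected-output tables.

Every censor date, event and outcome below is derived BY HAND from the
analysis rules (the comments show the arithmetic); the covered-day counts
come from the brute-force day-grid oracle, not from the package's interval
engine.  Run from the repository root:

    python scripts/regen_fixture_expected.py

writes tests/data/worked_fixture_expected_{streams,periods,five_year}.csv.
"""

from __future__ import annotations

import csv
import datetime as dt
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from daygrid import daygrid_covered_days  # noqa: E402

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "tests" / "data"

MET_SCD = 37
SU_SCD = 33


def d(s: str) -> int:
    return dt.date.fromisoformat(s).toordinal()


def iso(o: int) -> str:
    return dt.date.fromordinal(o).isoformat()


def days(start: str, step: int, count: int) -> list[int]:
    return [d(start) + step * k for k in range(count)]


# Analysis-window supply streams (baseline records excluded by rule).
STREAMS = {
    # F01: prevalent; 69 supplies every 37 d from 2013-01-05; persists to study end.
    ("F01", "metformin"): days("2013-01-05", 37, 69),
    # F02: incident; 8 supplies every 74 d from 2014-03-01; terminal gap > 365 d,
    # no other class -> discontinued; censor = last (2015-08-01) + 37 = 2015-09-07.
    ("F02", "metformin"): days("2014-03-01", 74, 8),
    # F03: single record -> intolerance flag, ineligible for PDC.
    ("F03", "metformin"): [d("2013-05-10")],
    # F04: 3 supplies then a 433-d gap (restart: 2014 records excluded);
    # censor = 2013-03-25 + 37 = 2013-05-01, discontinued.
    ("F04", "metformin"): [d("2013-01-10"), d("2013-02-16"), d("2013-03-25"),
                           d("2014-06-01"), d("2014-07-08")],
    # F05: metformin stops 2013-04-16; sulfonylurea starts 2013-06-01 (after the
    # last metformin supply) -> switched; censor = 2013-04-16 + 37 = 2013-05-23.
    ("F05", "metformin"): [d("2013-02-01"), d("2013-03-10"), d("2013-04-16")],
    # F05 sulfonylurea: 10 supplies every 33 d; terminal gap > 365, no later
    # other-class record -> discontinued; censor = 2014-03-25 + 33 = 2014-04-27.
    ("F05", "sulfonylurea"): days("2013-06-01", 33, 10),
    # F06: dies 2015-06-30, 3 d after the last supply (gap <= 365) -> death
    # censoring at the death date.
    ("F06", "metformin"): days("2013-01-20", 37, 25),
    # F07: gap of exactly 365 d (NOT a discontinuation: rule is strict >365);
    # then terminal gap -> discontinued; censor = 2014-01-01 + 37 = 2014-02-07.
    ("F07", "metformin"): [d("2013-01-01"), d("2014-01-01")],
}

# Hand-derived stream-level expectations.
STREAM_EXPECT = [
    # pid, class, n_records, single_flag, eligible, index, censor, event
    ("F01", "metformin", 69, 0, 1, "2013-01-05", "2019-12-31", "study_end"),
    ("F02", "metformin", 8, 0, 1, "2014-03-01", "2015-09-07", "discontinued"),
    ("F03", "metformin", 1, 1, 0, "2013-05-10", "2013-06-16", "discontinued"),
    ("F04", "metformin", 5, 0, 1, "2013-01-10", "2013-05-01", "discontinued"),
    ("F05", "metformin", 3, 0, 1, "2013-02-01", "2013-05-23", "switched"),
    ("F05", "sulfonylurea", 10, 0, 1, "2013-06-01", "2014-04-27", "discontinued"),
    ("F06", "metformin", 25, 0, 1, "2013-01-20", "2015-06-30", "death"),
    ("F07", "metformin", 2, 0, 1, "2013-01-01", "2014-02-07", "discontinued"),
]

# Hand-derived period layout: (pid, class, retained_count, scd, censor, event,
# outcome mapping is full until the period containing the censor).
PERIODS = [
    # (pid, cls, scd, retained_supplies, censor_iso, outcome_if_truncated)
    ("F01", "metformin", MET_SCD, STREAMS[("F01", "metformin")], "2019-12-31", "full"),
    ("F02", "metformin", MET_SCD, STREAMS[("F02", "metformin")], "2015-09-07", "discontinued"),
    ("F04", "metformin", MET_SCD, STREAMS[("F04", "metformin")][:3], "2013-05-01", "discontinued"),
    ("F05", "metformin", MET_SCD, STREAMS[("F05", "metformin")], "2013-05-23", "switched"),
    ("F05", "sulfonylurea", SU_SCD, STREAMS[("F05", "sulfonylurea")], "2014-04-27", "discontinued"),
    ("F06", "metformin", MET_SCD, STREAMS[("F06", "metformin")], "2015-06-30", "died_or_study_end"),
    ("F07", "metformin", MET_SCD, STREAMS[("F07", "metformin")], "2014-02-07", "discontinued"),
]


def anniversary(index: dt.date, k: int) -> dt.date:
    try:
        return index.replace(year=index.year + k)
    except ValueError:
        return dt.date(index.year + k, 3, 1)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    with open(OUT / "worked_fixture_expected_streams.csv", "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["participant_id", "drug_class", "n_records",
                      "single_record_flag", "eligible", "index_date",
                      "censor_date", "event"])
        wtr.writerows(STREAM_EXPECT)

    period_rows = []
    five_rows = []
    for pid, cls, scd, supplies, censor_iso, trunc_outcome in PERIODS:
        index = dt.date.fromordinal(supplies[0])
        cap = d(censor_iso) + 1  # censor date itself is analysable
        for k in range(1, 6):
            ps = anniversary(index, k - 1).toordinal()
            pe = anniversary(index, k).toordinal()
            if ps >= cap:
                break
            analysis_end = min(pe, cap)
            covered = daygrid_covered_days(supplies, scd, ps, analysis_end, cap=cap)
            analysis_days = analysis_end - ps
            # full iff the censor falls strictly after the period end; study-end
            # censoring coinciding with the period end also counts as full
            if trunc_outcome == "full":  # persistent to study end
                outcome = "full" if pe <= cap else "died_or_study_end"
            else:
                outcome = "full" if pe < cap else trunc_outcome
            pdc = covered / analysis_days
            period_rows.append([pid, cls, k, iso(ps), iso(pe), analysis_days,
                                covered, f"{pdc:.10f}", int(pdc >= 0.8), outcome])
        pe5 = anniversary(index, 5).toordinal()
        if cap >= pe5:
            covered5 = daygrid_covered_days(supplies, scd, index.toordinal(), pe5, cap=cap)
            days5 = pe5 - index.toordinal()
            pdc5 = covered5 / days5
            five_rows.append([pid, cls, days5, covered5, f"{pdc5:.10f}",
                              int(pdc5 >= 0.8)])

    with open(OUT / "worked_fixture_expected_periods.csv", "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["participant_id", "drug_class", "period_index",
                      "period_start", "period_end", "analysis_days",
                      "covered_days", "pdc", "adherent", "outcome"])
        wtr.writerows(period_rows)

    with open(OUT / "worked_fixture_expected_five_year.csv", "w", newline="") as fh:
        wtr = csv.writer(fh)
        wtr.writerow(["participant_id", "drug_class", "analysis_days",
                      "covered_days", "pdc_5y", "adherent_5y"])
        wtr.writerows(five_rows)

    print(f"wrote {len(STREAM_EXPECT)} stream rows, {len(period_rows)} period rows, "
          f"{len(five_rows)} five-year rows to {OUT}")


if __name__ == "__main__":
    main()
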