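"""Core adherence computation.

For each participant-and-drug-class stream of dispensing dates (analysis
window only; baseline records never enter PDC):

1. *Restart exclusion*: records after the first same-class gap strictly
   greater than ``gap_days`` (default 365) are dropped.
2. *Eligibility*: at least two retained records (the second is necessarily
   within 12 months of the first after restart exclusion).  A participant
   with exactly one record ever is flagged as a possible intolerance case.
3. *Persistence / censoring*: the stream ends at the earliest of the study
   end, death, or — when a >12-month gap shows the class was stopped —
   the last supply plus the class's standard coverage days.  A stop is a
   *switch* when any other drug class (including insulin/acarbose) was
   dispensed after the last supply of the class under study, otherwise a
   *discontinuation*.
4. *Periods*: twelve-month periods anchored at the index date (first supply
   on/after the analysis start), calendar-anniversary boundaries, half-open;
   up to ``max_periods``.  PDC = covered days / analysis days within the
   (possibly censor-truncated) period.
5. *Five-year PDC* for participants whose stream survives all five periods.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ClassMap, StudyWindow
from .coverage import CoverageTimeline, build_coverage, covered_days

OUTCOME_FULL = "full"
OUTCOME_DIED_OR_END = "died_or_study_end"
OUTCOME_DISCONTINUED = "discontinued"
OUTCOME_SWITCHED = "switched"

_EVENT_OUTCOME = {
    "study_end": OUTCOME_DIED_OR_END,
    "death": OUTCOME_DIED_OR_END,
    "discontinued": OUTCOME_DISCONTINUED,
    "switched": OUTCOME_SWITCHED,
}

ADHERENCE_CATEGORIES = ("strongly_nonadherent", "nonadherent", "adherent")


def categorize_pdc(pdc: float, threshold: float = 0.8) -> str:
    """Adherence level: <0.5 strongly nonadherent, 0.5-<0.8 nonadherent,
    >=0.8 adherent (boundaries closed on the left)."""
    if not 0 <= pdc <= 1:
        raise ValueError(f"pdc out of range: {pdc}")
    if pdc >= threshold:
        return "adherent"
    if pdc >= 0.5:
        return "nonadherent"
    return "strongly_nonadherent"


def anniversary(index_date: dt.date, k: int) -> dt.date:
    """index_date + k calendar years, month/day preserved; a 29 Feb index
    maps to 1 Mar in non-leap years."""
    try:
        return index_date.replace(year=index_date.year + k)
    except ValueError:  # 29 Feb
        return dt.date(index_date.year + k, 3, 1)


def exclude_restarts(
    ordinals: Sequence[int], gap_days: int = 365
) -> tuple[list[int], bool]:
    """Drop all records after the first internal gap > ``gap_days``.

    Returns (retained records, whether any were dropped).  The strict
    inequality means a gap of exactly ``gap_days`` is not a restart.
    """
    retained = [ordinals[0]] if ordinals else []
    for prev, cur in zip(ordinals, ordinals[1:]):
        if cur - prev > gap_days:
            return retained, True
        retained.append(cur)
    return retained, False


def eligibility_for_pdc(
    ordinals: Sequence[int], gap_days: int = 365
) -> tuple[bool, bool]:
    """(eligible, single_record_flag) for a same-class record stream.

    Eligible: >=2 records with the second within ``gap_days`` of the first
    (records beyond a restart gap never count).  The single-record flag marks
    exactly one record ever — a possible intolerance case.
    """
    retained, _ = exclude_restarts(sorted(ordinals), gap_days)
    return len(retained) >= 2, len(ordinals) == 1


def detect_discontinuation(
    class_ordinals: Sequence[int],
    other_ordinals: Sequence[int],
    horizon: int,
    gap_days: int = 365,
) -> list[tuple[int, str]]:
    """All same-class gaps > ``gap_days``, each with its disposition.

    Gaps are between consecutive records and from the last record to
    ``horizon`` (the inclusive end of follow-up while alive).  Disposition is
    ``switched`` when any other-class record is dated strictly after the gap
    start, else ``discontinued``.
    """
    others = np.asarray(sorted(other_ordinals))
    events: list[tuple[int, str]] = []

    def disposition(gap_start: int) -> str:
        later = others.searchsorted(gap_start, side="right") < len(others)
        return "switched" if later else "discontinued"

    for prev, cur in zip(class_ordinals, class_ordinals[1:]):
        if cur - prev > gap_days:
            events.append((prev, disposition(prev)))
    if class_ordinals and horizon - class_ordinals[-1] > gap_days:
        events.append((class_ordinals[-1], disposition(class_ordinals[-1])))
    return events


@dataclass(frozen=True)
class PersistenceResult:
    """How and when a participant-class stream ends."""

    event: str  # study_end | death | discontinued | switched
    censor_date: dt.date  # inclusive last analysable day
    censor_exclusive: int  # ordinal of the first non-analysable day
    last_supply: dt.date
    restart_excluded: bool


def classify_persistence(
    retained: Sequence[int],
    restart_excluded: bool,
    other_ordinals: Sequence[int],
    death_ordinal: int | None,
    scd_days: int,
    window: StudyWindow,
) -> PersistenceResult:
    """Determine the stream-ending event and the censor date.

    Censor = min(study end, death, last supply + SCD for streams that
    discontinued or switched).  A stop within ``gap_days`` of death is death
    censoring, not a discontinuation (the participant was not alive over the
    would-be gap).
    """
    last = retained[-1]
    study_end = window.study_end.toordinal()
    horizon = study_end if death_ordinal is None else min(study_end, death_ordinal)
    gap = restart_excluded or (horizon - last > window.gap_days)
    if gap:
        others = sorted(other_ordinals)
        switched = bool(others) and others[-1] > last
        event = "switched" if switched else "discontinued"
        censor = min(last + scd_days, horizon)
    elif death_ordinal is not None and death_ordinal <= study_end:
        event, censor = "death", death_ordinal
    else:
        event, censor = "study_end", study_end
    return PersistenceResult(
        event=event,
        censor_date=dt.date.fromordinal(censor),
        censor_exclusive=censor + 1,
        last_supply=dt.date.fromordinal(last),
        restart_excluded=restart_excluded,
    )


def determine_censor_date(
    class_ordinals: Sequence[int],
    other_ordinals: Sequence[int],
    death_date: dt.date | None,
    scd_days: int,
    window: StudyWindow | None = None,
) -> tuple[dt.date, str]:
    """Convenience wrapper: (censor date, event) for a raw record stream."""
    window = window or StudyWindow()
    ords = sorted(class_ordinals)
    retained, dropped = exclude_restarts(ords, window.gap_days)
    res = classify_persistence(
        retained,
        dropped,
        other_ordinals,
        death_date.toordinal() if death_date else None,
        scd_days,
        window,
    )
    return res.censor_date, res.event


def compute_period_results(
    timeline: CoverageTimeline,
    persistence: PersistenceResult,
    window: StudyWindow,
) -> list[dict]:
    """Per-12-month-period analysis days, PDC, adherence and outcome.

    A period is emitted iff it starts before the censor bound; its analysis
    window is truncated at the censor.  Outcome is ``full`` when the censor
    falls strictly after the period end (or coincides with it through the
    administrative study end); otherwise the censoring event's outcome.  A
    death on the period's final day therefore yields full analysis days with
    outcome ``died_or_study_end``.
    """
    index = dt.date.fromordinal(timeline.index_date)
    cap = persistence.censor_exclusive
    rows = []
    for k in range(1, window.max_periods + 1):
        ps = anniversary(index, k - 1).toordinal()
        pe = anniversary(index, k).toordinal()
        if ps >= cap:
            break
        analysis_end = min(pe, cap)
        analysis_days = analysis_end - ps
        covered = covered_days(timeline.intervals, ps, analysis_end)
        pdc = covered / analysis_days
        if pe < cap or (pe == cap and persistence.event == "study_end"):
            outcome = OUTCOME_FULL
        else:
            outcome = _EVENT_OUTCOME[persistence.event]
        rows.append(
            {
                "period_index": k,
                "period_start": dt.date.fromordinal(ps),
                "period_end": dt.date.fromordinal(pe),
                "analysis_days": analysis_days,
                "covered_days": covered,
                "pdc": pdc,
                "adherent": pdc >= window.adherence_threshold,
                "outcome": outcome,
            }
        )
    return rows


def compute_five_year(
    timeline: CoverageTimeline,
    persistence: PersistenceResult,
    window: StudyWindow,
) -> dict | None:
    """Whole-window PDC for streams that survive all ``max_periods`` periods."""
    index = dt.date.fromordinal(timeline.index_date)
    pe_last = anniversary(index, window.max_periods).toordinal()
    if persistence.censor_exclusive < pe_last:
        return None
    start = timeline.index_date
    analysis_days = pe_last - start
    covered = covered_days(timeline.intervals, start, pe_last)
    pdc = covered / analysis_days
    return {
        "analysis_days": analysis_days,
        "covered_days": covered,
        "pdc_5y": pdc,
        "adherent_5y": pdc >= window.adherence_threshold,
    }


@dataclass
class ParticipantClassResult:
    participant_id: str
    class_name: str
    n_records: int
    single_record_flag: bool
    eligible: bool
    index_date: dt.date | None
    persistence: PersistenceResult | None
    periods: list[dict]
    five_year: dict | None


def analyze_participant_class(
    participant_id: str,
    class_name: str,
    class_ordinals: Sequence[int],
    other_ordinals: Sequence[int],
    death_date: dt.date | None,
    scd_days: int,
    window: StudyWindow | None = None,
    coverage_model: str = "stockpile",
) -> ParticipantClassResult:
    """Full per-stream analysis; ``class_ordinals`` must already be
    restricted to the analysis window (baseline records excluded)."""
    window = window or StudyWindow()
    ords = sorted(class_ordinals)
    n_records = len(ords)
    if n_records == 0:
        return ParticipantClassResult(
            participant_id, class_name, 0, False, False, None, None, [], None
        )
    retained, restart_dropped = exclude_restarts(ords, window.gap_days)
    eligible = len(retained) >= 2
    single_flag = n_records == 1
    death_ord = death_date.toordinal() if death_date else None
    persistence = classify_persistence(
        retained, restart_dropped, other_ordinals, death_ord, scd_days, window
    )
    periods: list[dict] = []
    five: dict | None = None
    if eligible:
        timeline = build_coverage(
            participant_id,
            class_name,
            retained,
            scd_days,
            persistence.censor_exclusive,
            model=coverage_model,
        )
        periods = compute_period_results(timeline, persistence, window)
        five = compute_five_year(timeline, persistence, window)
    return ParticipantClassResult(
        participant_id=participant_id,
        class_name=class_name,
        n_records=n_records,
        single_record_flag=single_flag,
        eligible=eligible,
        index_date=dt.date.fromordinal(retained[0]),
        persistence=persistence,
        periods=periods,
        five_year=five,
    )


def run_adherence(
    resolved_dispensing: pd.DataFrame,
    participants: pd.DataFrame,
    class_map: ClassMap,
    window: StudyWindow | None = None,
    classes: Iterable[str] | None = None,
    coverage_model: str = "stockpile",
    stream_mask: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the adherence engine over every participant-class stream.

    ``stream_mask`` optionally restricts which resolved rows may form the
    analysed supply streams (e.g. fixed-dose-combination-only subgroups);
    switch detection always sees all records.  Returns
    (period_results, five_year, participant_class) frames.
    """
    window = window or StudyWindow()
    classes = tuple(classes) if classes is not None else class_map.pdc_classes()

    disp = resolved_dispensing
    dates = disp["date_of_supply"].dt.date
    in_analysis = (dates >= window.analysis_start) & (dates <= window.study_end)
    analysis = disp[in_analysis]
    ords_all = analysis["date_of_supply"].map(lambda d: d.toordinal())
    by_pid_class: dict[tuple[str, str], list[int]] = {
        k: sorted(v)
        for k, v in ords_all.groupby(
            [analysis["participant_id"], analysis["drug_class"]]
        ).agg(list).items()
    }
    by_pid: dict[str, dict[str, list[int]]] = {}
    for (pid, cls), v in by_pid_class.items():
        by_pid.setdefault(pid, {})[cls] = v
    if stream_mask is not None:
        masked = analysis[stream_mask.reindex(analysis.index, fill_value=False)]
        ords_masked = masked["date_of_supply"].map(lambda d: d.toordinal())
        stream_by_pid_class = {
            k: sorted(v)
            for k, v in ords_masked.groupby(
                [masked["participant_id"], masked["drug_class"]]
            ).agg(list).items()
        }
    else:
        stream_by_pid_class = by_pid_class

    death_by_pid = {
        r.participant_id: (None if pd.isna(r.death_date) else r.death_date.date())
        for r in participants.itertuples()
    }
    pids = set(participants["participant_id"])

    period_rows, five_rows, pc_rows = [], [], []
    for (pid, cls), stream in stream_by_pid_class.items():
        if cls not in classes or pid not in pids:
            continue
        other = sorted(
            o for c2, v in by_pid.get(pid, {}).items() if c2 != cls for o in v
        )
        res = analyze_participant_class(
            pid,
            cls,
            stream,
            other,
            death_by_pid.get(pid),
            class_map.get(cls).scd_days,
            window,
            coverage_model,
        )
        pc_rows.append(
            {
                "participant_id": pid,
                "drug_class": cls,
                "n_records": res.n_records,
                "single_record_flag": res.single_record_flag,
                "eligible": res.eligible,
                "index_date": res.index_date,
                "censor_date": res.persistence.censor_date if res.persistence else None,
                "event": res.persistence.event if res.persistence else None,
            }
        )
        for row in res.periods:
            period_rows.append({"participant_id": pid, "drug_class": cls, **row})
        if res.five_year is not None:
            five_rows.append({"participant_id": pid, "drug_class": cls, **res.five_year})

    period_df = pd.DataFrame(
        period_rows,
        columns=[
            "participant_id",
            "drug_class",
            "period_index",
            "period_start",
            "period_end",
            "analysis_days",
            "covered_days",
            "pdc",
            "adherent",
            "outcome",
        ],
    )
    five_df = pd.DataFrame(
        five_rows,
        columns=[
            "participant_id",
            "drug_class",
            "analysis_days",
            "covered_days",
            "pdc_5y",
            "adherent_5y",
        ],
    )
    pc_df = pd.DataFrame(
        pc_rows,
        columns=[
            "participant_id",
            "drug_class",
            "n_records",
            "single_record_flag",
            "eligible",
            "index_date",
            "censor_date",
            "event",
        ],
    )
    return period_df, five_df, pc_df
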