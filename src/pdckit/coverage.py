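"""Medication-on-hand coverage timelines from dated supply events.

Dates are handled as proleptic-Gregorian day ordinals (``datetime.date
.toordinal``); intervals are half-open ``[start, end)`` so interval lengths
and day counts coincide and adjacent intervals merge cleanly.

Two coverage models are provided:

``stockpile``
    Each supply adds ``scd`` days of coverage beginning at the later of the
    supply date and the end of current coverage, i.e. early refills are
    banked and never overlap (carry-forward).  Same-day duplicate supplies
    each add ``scd`` days.
``union``
    Each supply covers ``[supply, supply + scd)`` and overlapping coverage is
    discarded (no carryover); available for sensitivity analyses.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

Interval = tuple[int, int]  # half-open [start, end) in day ordinals

COVERAGE_MODELS = ("stockpile", "union")


def to_ordinal(d: dt.date | int) -> int:
    return d if isinstance(d, int) else d.toordinal()


def build_intervals(
    supply_ordinals: Sequence[int],
    scd_days: int,
    cap: int | None = None,
    model: str = "stockpile",
) -> list[Interval]:
    """Merge supplies into sorted, non-overlapping coverage intervals.

    ``cap`` is an exclusive upper bound (censoring); coverage at or beyond it
    is discarded.  Supplies must be sorted ascending.
    """
    if scd_days <= 0:
        raise ValueError("scd_days must be positive")
    if model not in COVERAGE_MODELS:
        raise ValueError(f"unknown coverage model {model!r}")
    intervals: list[Interval] = []
    prev_supply: int | None = None
    for s in supply_ordinals:
        if prev_supply is not None and s < prev_supply:
            raise ValueError("supplies not sorted")
        prev_supply = s
        cover_end = intervals[-1][1] if intervals else None
        if model == "stockpile":
            # coverage begins when the previous box runs out (carry-forward)
            start = s if cover_end is None or s > cover_end else cover_end
            end = start + scd_days
        else:  # union: a refill restarts the clock, overlap is discarded
            start, end = s, s + scd_days
        if intervals and start <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], end))
        else:
            intervals.append((start, end))
    if cap is not None:
        intervals = [(a, min(b, cap)) for a, b in intervals if a < cap]
        intervals = [(a, b) for a, b in intervals if b > a]
    return intervals


def covered_days(intervals: Iterable[Interval], start: int, end: int) -> int:
    """Number of covered days within the half-open window [start, end)."""
    total = 0
    for a, b in intervals:
        lo, hi = max(a, start), min(b, end)
        if hi > lo:
            total += hi - lo
    return total


@dataclass(frozen=True)
class CoverageTimeline:
    """Per participant-and-class coverage: ordered medication-on-hand intervals.

    ``index_date`` is the first supply of the class on/after the analysis
    start and anchors the 12-month analysis periods.
    """

    participant_id: str
    class_name: str
    intervals: tuple[Interval, ...]
    index_date: int
    last_supply_date: int

    @property
    def total_covered_days(self) -> int:
        return sum(b - a for a, b in self.intervals)


def build_coverage(
    participant_id: str,
    class_name: str,
    supply_ordinals: Sequence[int],
    scd_days: int,
    censor_exclusive: int,
    model: str = "stockpile",
) -> CoverageTimeline:
    """Build a coverage timeline truncated at an exclusive censor bound."""
    if not supply_ordinals:
        raise ValueError("empty supply list")
    intervals = build_intervals(supply_ordinals, scd_days, cap=censor_exclusive, model=model)
    return CoverageTimeline(
        participant_id=participant_id,
        class_name=class_name,
        intervals=tuple(intervals),
        index_date=supply_ordinals[0],
        last_supply_date=supply_ordinals[-1],
    )
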