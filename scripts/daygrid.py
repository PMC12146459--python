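"""Brute-force day-grid coverage oracle.

Simulates a pill-box one day at a time: each supply adds (stockpile) or
resets (union) the tablets on hand; a day is covered when at least one
tablet remains, and one tablet is consumed per covered day.  This is the
independent check for the interval-arithmetic coverage engine and the
generator of the worked fixture's expected PDC values.  Deliberately slow
and obvious; kept outside the package so it can never be confused with the
implementation it verifies.
"""

from __future__ import annotations

from typing import Sequence


def daygrid_covered_days(
    supply_ordinals: Sequence[int],
    scd_days: int,
    window_start: int,
    window_end: int,  # exclusive
    cap: int | None = None,  # exclusive censor bound
    model: str = "stockpile",
) -> int:
    """Covered days in [window_start, window_end) by day-by-day simulation."""
    if not supply_ordinals:
        return 0
    supplies = sorted(supply_ordinals)
    stop = window_end if cap is None else min(window_end, cap)
    first = supplies[0]
    tablets = 0
    covered = 0
    i = 0
    day = first
    end = stop if cap is None else max(stop, window_end)
    while day < max(window_end, stop):
        while i < len(supplies) and supplies[i] == day:
            if model == "stockpile":
                tablets += scd_days
            else:  # union: a refill tops the box back up to one full supply
                tablets = scd_days
            i += 1
        on_hand = tablets > 0
        in_cap = cap is None or day < cap
        if on_hand:
            tablets -= 1
            if window_start <= day < window_end and in_cap:
                covered += 1
        day += 1
    return covered


def daygrid_pdc(
    supply_ordinals: Sequence[int],
    scd_days: int,
    period_start: int,
    period_end: int,
    cap: int | None = None,
    model: str = "stockpile",
) -> float:
    end = period_end if cap is None else min(period_end, cap)
    days = end - period_start
    if days <= 0:
        raise ValueError("empty analysis window")
    return (
        daygrid_covered_days(
            supply_ordinals, scd_days, period_start, period_end, cap, model
        )
        / days
    )
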