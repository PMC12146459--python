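"""Cohort construction: exclusion cascade and baseline user status.

Exclusions are applied sequentially, in the study's order, and each
participant is counted at the FIRST step they fail (flow-diagram
accounting):

1. withdrew from the study;
2. never self-reported diabetes;
3. died before the analysis start (death_date < 2013-01-01);
4. only ever dispensed acarbose and/or insulin;
5. no glucose-lowering-medication record on/after the analysis start.

Baseline status per drug class: *prevalent* if the participant has at least
one dispensing of the class inside the baseline window (inclusive at both
ends), *incident* if none in the baseline window but at least one after it,
*nonuser* otherwise.  Baseline-window records are used only for this
classification, never for PDC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .config import StudyWindow

EXCLUSION_STEPS = (
    "withdrew",
    "no_self_reported_diabetes",
    "died_before_analysis_start",
    "acarbose_or_insulin_only",
    "no_glm_after_analysis_start",
)


@dataclass(frozen=True)
class CohortFlow:
    """Counts at each exclusion step; conserves the input total."""

    initial_total: int
    withdrew: int
    no_self_reported_diabetes: int
    died_before_analysis_start: int
    acarbose_or_insulin_only: int
    no_glm_after_analysis_start: int
    analysed: int

    def __post_init__(self) -> None:
        excluded = sum(getattr(self, s) for s in EXCLUSION_STEPS)
        if self.initial_total != self.analysed + excluded:
            raise ValueError("cohort flow does not conserve the input total")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def build_cohort(
    participants: pd.DataFrame,
    resolved_dispensing: pd.DataFrame,
    window: StudyWindow | None = None,
    censor_only_classes: tuple[str, ...] = ("insulin", "acarbose"),
) -> tuple[pd.DataFrame, CohortFlow]:
    """Apply the exclusion cascade; return (analysed participants, flow)."""
    window = window or StudyWindow()
    if participants.empty:
        warnings.warn("empty participant table: empty cohort", stacklevel=2)
        flow = CohortFlow(0, 0, 0, 0, 0, 0, 0)
        return participants.copy(), flow

    disp = resolved_dispensing
    classes_by_pid = disp.groupby("participant_id")["drug_class"].agg(set)
    has_record_since = set(
        disp.loc[
            disp["date_of_supply"].dt.date >= window.analysis_start, "participant_id"
        ]
    )

    remaining = participants
    counts = {}

    step1 = remaining["withdrew"]
    counts["withdrew"] = int(step1.sum())
    remaining = remaining[~step1]

    step2 = ~remaining["diabetes"]
    counts["no_self_reported_diabetes"] = int(step2.sum())
    remaining = remaining[~step2]

    step3 = remaining["death_date"] < pd.Timestamp(window.analysis_start)
    counts["died_before_analysis_start"] = int(step3.sum())
    remaining = remaining[~step3]

    pid_classes = remaining["participant_id"].map(classes_by_pid)
    step4 = pid_classes.map(
        lambda s: isinstance(s, set) and len(s) > 0 and s <= set(censor_only_classes)
    )
    counts["acarbose_or_insulin_only"] = int(step4.sum())
    remaining = remaining[~step4]

    step5 = ~remaining["participant_id"].isin(has_record_since)
    counts["no_glm_after_analysis_start"] = int(step5.sum())
    remaining = remaining[~step5]

    flow = CohortFlow(
        initial_total=len(participants), analysed=len(remaining), **counts
    )
    return remaining.reset_index(drop=True), flow


def classify_user_status(
    participant_id: str,
    class_name: str,
    class_dates: pd.Series,
    window: StudyWindow | None = None,
) -> str:
    """Baseline status for one participant-class: prevalent/incident/nonuser.

    ``class_dates`` are this participant's supply dates for this class only;
    record order and other classes' records are irrelevant.
    """
    window = window or StudyWindow()
    dates = pd.to_datetime(pd.Series(class_dates)).dt.date
    in_baseline = dates.between(window.baseline_start, window.baseline_end)
    if in_baseline.any():
        return "prevalent"
    if (dates > window.baseline_end).any():
        return "incident"
    return "nonuser"


def user_status_table(
    resolved_dispensing: pd.DataFrame,
    class_names: tuple[str, ...],
    window: StudyWindow | None = None,
) -> pd.DataFrame:
    """Vectorised status per (participant, class) with >=1 record.

    Participant-class pairs with no records at all (status ``nonuser``) are
    omitted; columns: participant_id, drug_class, user_status.
    """
    window = window or StudyWindow()
    disp = resolved_dispensing[resolved_dispensing["drug_class"].isin(class_names)]
    d = disp["date_of_supply"].dt.date
    grp = disp.assign(
        _baseline=d.between(window.baseline_start, window.baseline_end),
        _after=d > window.baseline_end,
    ).groupby(["participant_id", "drug_class"])[["_baseline", "_after"]].any()
    status = pd.Series("nonuser", index=grp.index)
    status[grp["_after"]] = "incident"
    status[grp["_baseline"]] = "prevalent"
    out = status.rename("user_status").reset_index()
    return out[out["user_status"] != "nonuser"].reset_index(drop=True)
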