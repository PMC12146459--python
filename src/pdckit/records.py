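"""Reading and validating participant and dispensing tables.

Input schema is a fixed CSV dialect: UTF-8, header row, ISO-8601 dates.

``participants.csv``
    participant_id, sex, age_2013, duration_group, ses_quintile, remoteness,
    death_date (blank if alive), withdrew (0/1), diabetes (0/1)
``dispensing.csv``
    participant_id, date_of_supply, atc_code, item_code

Dispensing records are resolved to analysed drug classes: exact/longest ATC
prefix match for single-agent products, the combination map for fixed-dose
combinations (one dispensing of EACH constituent class), and pharmacy item
codes for the ambiguous pre-2017 A10BX products.  Records before the capture
start are dropped; records whose code maps to no analysed class are excluded
and counted in the load report.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .config import ClassMap, StudyWindow

PARTICIPANT_COLUMNS = [
    "participant_id",
    "sex",
    "age_2013",
    "duration_group",
    "ses_quintile",
    "remoteness",
    "death_date",
    "withdrew",
    "diabetes",
]
DISPENSING_COLUMNS = ["participant_id", "date_of_supply", "atc_code", "item_code"]

SEXES = ("female", "male")
REMOTENESS_LEVELS = ("major city", "inner regional", "outer regional/remote")
DURATION_GROUPS = ("<10y", "10-19y", ">=20y")


class UnmappedA10BXError(ValueError):
    """An A10BX record whose item code has no class override."""


def resolve_class(
    atc_code: str, item_code: str | None, class_map: ClassMap
) -> frozenset[str]:
    """Resolve an ATC (+ optional item) code to a set of analysed classes.

    Returns the empty set for codes outside the analysed classes.  A10BX
    records with an unknown item code raise :class:`UnmappedA10BXError`
    because silently guessing between GLP1RA and SGLT2i would corrupt both
    classes' results.
    """
    if not atc_code:
        raise ValueError("empty atc_code")
    atc_code = atc_code.strip().upper()
    if atc_code.startswith("A10BX"):
        item = (item_code or "").strip()
        cls = class_map.item_overrides.get(item)
        if cls is None:
            raise UnmappedA10BXError(
                f"A10BX record with item code {item or '<missing>'!r} has no "
                "class override; add it to the class map's item_overrides"
            )
        return frozenset({cls})
    if atc_code.startswith("A10BD"):
        members = class_map.combination_map.get(atc_code)
        return members if members is not None else frozenset()
    for prefix, name in class_map.prefix_table():
        if atc_code.startswith(prefix):
            return frozenset({name})
    return frozenset()


@dataclass(frozen=True)
class LoadReport:
    """Row accounting for one dispensing-table load."""

    n_rows: int
    n_dropped_pre_capture: int
    n_unmapped: int
    n_retained: int
    n_resolved_rows: int  # after combination expansion

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _parse_dates(series: pd.Series, colname: str) -> pd.Series:
    parsed = pd.to_datetime(series, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax())
        raise ValueError(
            f"malformed {colname} at row {row + 2} (1-based, incl. header): "
            f"{series[bad].iloc[0]!r}"
        )
    return parsed


def load_participants(path: str | Path) -> pd.DataFrame:
    """Load and validate the participant table."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(PARTICIPANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"participants file missing columns {sorted(missing)}")
    if df["participant_id"].duplicated().any():
        dup = df.loc[df["participant_id"].duplicated(), "participant_id"].iloc[0]
        raise ValueError(f"duplicate participant_id {dup!r}")
    df = df.copy()
    df["death_date"] = _parse_dates(df["death_date"], "death_date")
    df["withdrew"] = df["withdrew"].astype(int).astype(bool)
    df["diabetes"] = df["diabetes"].astype(int).astype(bool)
    df["age_2013"] = df["age_2013"].astype(int)
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(f"unknown sex value {df.loc[bad_sex, 'sex'].iloc[0]!r}")
    df["ses_quintile"] = df["ses_quintile"].astype(int)
    if not df["ses_quintile"].between(1, 5).all():
        raise ValueError("ses_quintile must be in 1..5")
    return df


def load_dispensing(
    path: str | Path,
    class_map: ClassMap,
    window: StudyWindow | None = None,
) -> tuple[pd.DataFrame, LoadReport]:
    """Load the dispensing table and resolve drug classes.

    Returns a long-format frame with one row per (record, resolved class):
    columns ``record_id, participant_id, date_of_supply, atc_code,
    item_code, drug_class``; plus a :class:`LoadReport`.  Duplicate identical
    rows are retained as distinct dispensings (same-day supplies stockpile).
    """
    window = window or StudyWindow()
    df = pd.read_csv(path, dtype={"participant_id": str, "item_code": str})
    missing = set(DISPENSING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dispensing file missing columns {sorted(missing)}")
    df = df.copy()
    df["date_of_supply"] = _parse_dates(df["date_of_supply"], "date_of_supply")
    if df["date_of_supply"].isna().any():
        row = int(df["date_of_supply"].isna().idxmax())
        raise ValueError(f"missing date_of_supply at row {row + 2}")
    n_rows = len(df)
    df["record_id"] = range(n_rows)

    keep = df["date_of_supply"].dt.date >= window.capture_start
    n_dropped = int((~keep).sum())
    df = df.loc[keep]

    resolved = resolve_frame(df, class_map)
    retained_ids = resolved["record_id"].nunique()
    report = LoadReport(
        n_rows=n_rows,
        n_dropped_pre_capture=n_dropped,
        n_unmapped=len(df) - retained_ids,
        n_retained=retained_ids,
        n_resolved_rows=len(resolved),
    )
    return resolved.reset_index(drop=True), report


def prepare_participants(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise an in-memory participant frame (as written by the
    generator) to the loaded representation: typed dates and booleans."""
    out = df.copy()
    dd = out["death_date"].astype(object)
    dd = dd.where(pd.Series(dd).astype(str).str.strip() != "", None)
    out["death_date"] = pd.to_datetime(dd, format="%Y-%m-%d")
    out["withdrew"] = out["withdrew"].astype(int).astype(bool)
    out["diabetes"] = out["diabetes"].astype(int).astype(bool)
    return out


def prepare_dispensing(
    df: pd.DataFrame,
    class_map: ClassMap,
    window: StudyWindow | None = None,
) -> pd.DataFrame:
    """Normalise and class-resolve an in-memory dispensing frame
    (capture-window filter included), mirroring :func:`load_dispensing`."""
    window = window or StudyWindow()
    out = df.copy()
    out["date_of_supply"] = pd.to_datetime(out["date_of_supply"])
    out["record_id"] = range(len(out))
    out = out[out["date_of_supply"].dt.date >= window.capture_start]
    return resolve_frame(out, class_map).reset_index(drop=True)


def resolve_frame(df: pd.DataFrame, class_map: ClassMap) -> pd.DataFrame:
    """Vectorised class resolution; explodes combinations to one row/class."""
    codes = df[["atc_code", "item_code"]].drop_duplicates()
    mapping: dict[tuple[str, str], frozenset[str]] = {}
    for atc, item in codes.itertuples(index=False):
        key = (atc, item if isinstance(item, str) else "")
        mapping[key] = resolve_class(atc, key[1], class_map)
    item_key = df["item_code"].where(df["item_code"].notna(), "")
    classes = [
        mapping[(a, i)] for a, i in zip(df["atc_code"], item_key)
    ]
    out = df.copy()
    out["drug_class"] = [sorted(c) for c in classes]
    out = out[out["drug_class"].map(len) > 0]
    out = out.explode("drug_class", ignore_index=True)
    return out
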