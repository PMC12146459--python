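"""Study-window and drug-class configuration.

The analysis is parameterised by four calendar anchors: the start of complete
dispensing capture (records before it are dropped), the baseline window used
to classify prevalent vs incident users, the start of the adherence analysis
window (index dates are the first supply on/after it), and the administrative
study end.  Defaults correspond to an Australian PBS claims study of
glucose-lowering medications (baseline Jul-Dec 2012, analysis 2013-2019) but
every anchor is a plain config value so the engine is reusable for other
windows.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

DATE_FMT = "%Y-%m-%d"


def parse_date(value: str | dt.date) -> dt.date:
    if isinstance(value, dt.date):
        return value
    return dt.datetime.strptime(str(value), DATE_FMT).date()


@dataclass(frozen=True)
class StudyWindow:
    """Calendar anchors and rule constants for one analysis run.

    ``gap_days`` realises the ">12 months" rule for discontinuation and
    restart detection: a gap is an event only when it is *strictly* greater
    than ``gap_days`` days.  ``adherence_threshold`` is the PDC cut-point for
    the adherent/non-adherent dichotomy.
    """

    capture_start: dt.date = dt.date(2012, 7, 1)
    baseline_start: dt.date = dt.date(2012, 7, 1)
    baseline_end: dt.date = dt.date(2012, 12, 31)  # inclusive
    analysis_start: dt.date = dt.date(2013, 1, 1)
    study_end: dt.date = dt.date(2019, 12, 31)  # inclusive
    gap_days: int = 365
    adherence_threshold: float = 0.8
    max_periods: int = 5

    def __post_init__(self) -> None:
        if not (
            self.capture_start
            <= self.baseline_start
            <= self.baseline_end
            < self.analysis_start
            <= self.study_end
        ):
            raise ValueError("study window anchors are not ordered")
        if self.gap_days <= 0 or self.max_periods <= 0:
            raise ValueError("gap_days and max_periods must be positive")
        if not 0 < self.adherence_threshold <= 1:
            raise ValueError("adherence_threshold must be in (0, 1]")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyWindow":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                kwargs[f.name] = parse_date(v) if "date" in str(f.type) else v
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.isoformat() if isinstance(v, dt.date) else v
        return out


@dataclass(frozen=True)
class ClassConfig:
    """Per-drug-class analysis parameters.

    ``scd_days`` is the standard coverage days: the number of days of
    medication on hand attributed to a single dispensing, defined as the
    median time to re-supply for the class.  ``pdc_eligible`` is False for
    classes whose daily dose varies too much for a meaningful PDC (insulin)
    or whose user base is too small (acarbose); their records still count for
    switch/discontinuation determination.
    """

    name: str
    atc_prefixes: tuple[str, ...]
    scd_days: int
    pdc_eligible: bool = True

    def __post_init__(self) -> None:
        if self.scd_days <= 0:
            raise ValueError(f"scd_days must be positive for class {self.name!r}")


# Analysed glucose-lowering medication classes.  Metformin 37 and
# sulfonylurea 33 standard coverage days are the published PBS medians; the
# once-daily classes default to 30.
DEFAULT_CLASSES: tuple[ClassConfig, ...] = (
    ClassConfig("metformin", ("A10BA02",), 37),
    ClassConfig("sulfonylurea", ("A10BB",), 33),
    ClassConfig("TZD", ("A10BG",), 30),
    ClassConfig("DPP4i", ("A10BH",), 30),
    ClassConfig("GLP1RA", ("A10BJ",), 30),
    ClassConfig("SGLT2i", ("A10BK",), 30),
    ClassConfig("insulin", ("A10A",), 30, pdc_eligible=False),
    ClassConfig("acarbose", ("A10BF01",), 30, pdc_eligible=False),
)

# Fixed-dose combinations (ATC A10BD) resolved to their analysed constituent
# classes.  A combination dispensing counts as one dispensing of EACH
# constituent.  A10BD14 (metformin+repaglinide) is absent because repaglinide
# is not an analysed class.
DEFAULT_COMBINATIONS: Mapping[str, frozenset[str]] = {
    "A10BD02": frozenset({"metformin", "sulfonylurea"}),
    "A10BD03": frozenset({"metformin", "TZD"}),
    "A10BD04": frozenset({"sulfonylurea", "TZD"}),
    "A10BD05": frozenset({"metformin", "TZD"}),
    "A10BD06": frozenset({"sulfonylurea", "TZD"}),
    "A10BD07": frozenset({"metformin", "DPP4i"}),
    "A10BD08": frozenset({"metformin", "DPP4i"}),
    "A10BD09": frozenset({"TZD", "DPP4i"}),
    "A10BD10": frozenset({"metformin", "DPP4i"}),
    "A10BD11": frozenset({"metformin", "DPP4i"}),
    "A10BD12": frozenset({"TZD", "DPP4i"}),
    "A10BD13": frozenset({"metformin", "DPP4i"}),
    "A10BD15": frozenset({"metformin", "SGLT2i"}),
    "A10BD16": frozenset({"metformin", "SGLT2i"}),
    "A10BD19": frozenset({"DPP4i", "SGLT2i"}),
    "A10BD20": frozenset({"metformin", "SGLT2i"}),
    "A10BD21": frozenset({"DPP4i", "SGLT2i"}),
    "A10BD23": frozenset({"metformin", "SGLT2i"}),
    "A10BD24": frozenset({"DPP4i", "SGLT2i"}),
    "A10BD25": frozenset({"metformin", "DPP4i", "SGLT2i"}),
}

# SYNTHETIC fixture: before 2017 both GLP1RA and SGLT2i products were coded
# A10BX, so A10BX records are resolved by pharmacy item code.  The real PBS
# item codes are not public in this form; these placeholder codes are a
# documented, user-overridable stand-in.
DEFAULT_A10BX_ITEMS: Mapping[str, str] = {
    "GLP1RA-X01": "GLP1RA",
    "GLP1RA-X02": "GLP1RA",
    "SGLT2I-X01": "SGLT2i",
    "SGLT2I-X02": "SGLT2i",
}


@dataclass(frozen=True)
class ClassMap:
    """Resolution tables from ATC/item codes to analysed drug classes."""

    classes: tuple[ClassConfig, ...] = DEFAULT_CLASSES
    combination_map: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_COMBINATIONS)
    )
    item_overrides: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_A10BX_ITEMS)
    )

    def __post_init__(self) -> None:
        names = self.class_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names")
        for code, members in self.combination_map.items():
            if len(members) < 2:
                raise ValueError(f"combination {code} must have >=2 constituents")
            unknown = set(members) - set(names)
            if unknown:
                raise ValueError(f"combination {code} names unknown classes {unknown}")
        for item, cls in self.item_overrides.items():
            if cls not in names:
                raise ValueError(f"item override {item} -> unknown class {cls!r}")

    def class_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    def get(self, name: str) -> ClassConfig:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(name)

    def pdc_classes(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes if c.pdc_eligible)

    def with_scd(self, overrides: Mapping[str, int]) -> "ClassMap":
        """Return a copy with per-class SCD overridden (sensitivity analyses)."""
        new = tuple(
            dataclasses.replace(c, scd_days=overrides[c.name])
            if c.name in overrides
            else c
            for c in self.classes
        )
        missing = set(overrides) - set(self.class_names())
        if missing:
            raise KeyError(f"scd override for unknown classes {sorted(missing)}")
        return dataclasses.replace(self, classes=new)

    def prefix_table(self) -> list[tuple[str, str]]:
        """(prefix, class) pairs sorted longest-prefix-first."""
        pairs = [(p, c.name) for c in self.classes for p in c.atc_prefixes]
        return sorted(pairs, key=lambda pc: -len(pc[0]))

    def to_dict(self) -> dict:
        return {
            "classes": [
                {
                    "name": c.name,
                    "atc_prefixes": list(c.atc_prefixes),
                    "scd_days": c.scd_days,
                    "pdc_eligible": c.pdc_eligible,
                }
                for c in self.classes
            ],
            "combination_map": {k: sorted(v) for k, v in self.combination_map.items()},
            "item_overrides": dict(self.item_overrides),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClassMap":
        classes = tuple(
            ClassConfig(
                name=c["name"],
                atc_prefixes=tuple(c["atc_prefixes"]),
                scd_days=int(c["scd_days"]),
                pdc_eligible=bool(c.get("pdc_eligible", True)),
            )
            for c in d["classes"]
        )
        return cls(
            classes=classes,
            combination_map={
                k: frozenset(v) for k, v in d.get("combination_map", {}).items()
            },
            item_overrides=dict(d.get("item_overrides", {})),
        )


def load_classmap(path: str | Path) -> ClassMap:
    """Load a ClassMap from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return ClassMap.from_dict(data)


def save_classmap(cmap: ClassMap, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cmap.to_dict(), indent=2))
    else:
        path.write_text(yaml.safe_dump(cmap.to_dict(), sort_keys=False))
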