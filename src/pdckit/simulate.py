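"""Synthetic participant and dispensing tables with known ground truth.

The generator emulates the statistical structure the adherence pipeline
assumes: per-drug-class streams of dated supply events with a per-participant
refill tempo, competing death / discontinuation / switch processes, prevalent
users with baseline-window records, and socio-demographic covariates that may
shift adherence.  It does NOT emulate PBS item-level pricing, brands or
copayments, seasonal refill patterns, or dose titration.

Refill model: each participant-class stream has an adherence propensity
``theta`` in (0, 1]; inter-supply gaps are ``round(scd / theta)`` days plus
integer jitter drawn uniformly from ±``jitter_days``, on a day grid.
``theta`` is drawn per participant (not per refill), either from a point-mass
mixture or from a two-point good/poor-refiller model whose probability of
being a good refiller is a logistic function of the covariates — that is the
ground truth the subgroup regression is meant to recover.

``truth.csv`` records the designed status, propensity and event dates per
stream; it is written for tests and is never read by the analysis pipeline.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .config import ClassMap, StudyWindow

SEXES = ("female", "male")
REMOTENESS = ("major city", "inner regional", "outer regional/remote")
DURATION_GROUPS = ("<10y", "10-19y", ">=20y")
AGE_GROUPS = ("45-54", "55-64", "65-74", ">=75")


@dataclass(frozen=True)
class ThetaModel:
    """Adherence-propensity model.

    ``kind="mixture"``: point masses ``components`` = ((weight, theta), ...).
    ``kind="logistic"``: participant is a good refiller (theta_good) with
    probability expit(logit(p_good) + sum of log-OR covariate effects),
    else a poor refiller (theta_poor).  ``effects`` maps covariate ->
    level -> odds multiplier on being a good refiller.
    """

    kind: str = "mixture"
    components: tuple[tuple[float, float], ...] = ((1.0, 0.9),)
    p_good: float = 0.6
    theta_good: float = 0.95
    theta_poor: float = 0.5
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def validate(self) -> list[str]:
        problems = []
        if self.kind not in ("mixture", "logistic"):
            problems.append(f"theta.kind: unknown {self.kind!r}")
        if self.kind == "mixture":
            w = sum(w for w, _ in self.components)
            if not math.isclose(w, 1.0, abs_tol=1e-9):
                problems.append("theta.components: weights must sum to 1")
            if any(not 0 < t <= 1 for _, t in self.components):
                problems.append("theta.components: theta must be in (0, 1]")
        else:
            for name, v in (("p_good", self.p_good),):
                if not 0 < v < 1:
                    problems.append(f"theta.{name}: must be in (0, 1)")
            for name, v in (
                ("theta_good", self.theta_good),
                ("theta_poor", self.theta_poor),
            ):
                if not 0 < v <= 1:
                    problems.append(f"theta.{name}: must be in (0, 1]")
            for cov, levels in self.effects.items():
                if any(or_ <= 0 for or_ in levels.values()):
                    problems.append(f"theta.effects[{cov}]: odds ratios must be > 0")
        return problems


@dataclass(frozen=True)
class ClassScenario:
    """Per-class uptake and event hazards.

    Hazards are per 12-month on-treatment period.  ``switch_to`` is the
    destination-class distribution used when a switch fires.
    """

    p_prevalent: float = 0.0
    p_incident: float = 0.0
    discontinuation_hazard: float = 0.0
    switch_hazard: float = 0.0
    switch_to: Mapping[str, float] = field(default_factory=dict)

    def validate(self, name: str) -> list[str]:
        problems = []
        for f_ in ("p_prevalent", "p_incident"):
            v = getattr(self, f_)
            if not 0 <= v <= 1:
                problems.append(f"classes[{name}].{f_}: must be in [0, 1]")
        if self.p_prevalent + self.p_incident > 1:
            problems.append(f"classes[{name}]: p_prevalent + p_incident > 1")
        for f_ in ("discontinuation_hazard", "switch_hazard"):
            v = getattr(self, f_)
            if not 0 <= v <= 1:
                problems.append(f"classes[{name}].{f_}: must be in [0, 1]")
        if self.switch_to:
            tot = sum(self.switch_to.values())
            if not math.isclose(tot, 1.0, abs_tol=1e-9):
                problems.append(f"classes[{name}].switch_to: must sum to 1")
        return problems


@dataclass(frozen=True)
class ScenarioConfig:
    """Full scenario: the seed and config determine the output exactly."""

    n_participants: int = 2000
    classes: Mapping[str, ClassScenario] = field(default_factory=dict)
    theta: ThetaModel = ThetaModel()
    jitter_days: int = 4
    annual_mortality: float = 0.02
    p_withdrew: float = 0.0
    p_no_diabetes: float = 0.0
    p_died_pre_analysis: float = 0.0
    p_censor_only_user: float = 0.0  # insulin-only users (excluded branch)
    incident_start: tuple[dt.date, dt.date] = (dt.date(2013, 1, 1), dt.date(2016, 12, 31))
    p_female: float = 0.43
    age_mean: float = 70.1
    age_sd: float = 9.8
    duration_probs: tuple[float, float, float] = (0.45, 0.35, 0.20)
    remoteness_probs: tuple[float, float, float] = (0.55, 0.30, 0.15)
    window: StudyWindow = StudyWindow()

    def validate(self) -> None:
        problems = []
        if self.n_participants <= 0:
            problems.append("n_participants: must be positive")
        if self.jitter_days < 0:
            problems.append("jitter_days: must be >= 0")
        for f_ in (
            "annual_mortality",
            "p_withdrew",
            "p_no_diabetes",
            "p_died_pre_analysis",
            "p_censor_only_user",
            "p_female",
        ):
            v = getattr(self, f_)
            if not 0 <= v <= 1:
                problems.append(f"{f_}: must be in [0, 1]")
        if not self.classes:
            problems.append("classes: at least one class scenario required")
        for name, cs in self.classes.items():
            problems.extend(cs.validate(name))
        problems.extend(self.theta.validate())
        if self.incident_start[0] < self.window.analysis_start:
            problems.append("incident_start: must begin on/after analysis_start")
        if problems:
            raise ValueError("invalid scenario config: " + "; ".join(problems))

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        kwargs = dict(d)
        if "classes" in kwargs:
            kwargs["classes"] = {
                k: ClassScenario(**{
                    kk: (dict(vv) if kk == "switch_to" else vv)
                    for kk, vv in v.items()
                })
                for k, v in kwargs["classes"].items()
            }
        if "theta" in kwargs:
            t = dict(kwargs["theta"])
            if "components" in t:
                t["components"] = tuple((float(w), float(th)) for w, th in t["components"])
            if "effects" in t:
                t["effects"] = {c: dict(l) for c, l in t["effects"].items()}
            kwargs["theta"] = ThetaModel(**t)
        if "incident_start" in kwargs:
            a, b = kwargs["incident_start"]
            kwargs["incident_start"] = (
                dt.date.fromisoformat(str(a)),
                dt.date.fromisoformat(str(b)),
            )
        if "window" in kwargs:
            kwargs["window"] = StudyWindow.from_dict(kwargs["window"])
        for tup in ("duration_probs", "remoteness_probs"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
        return cls(**kwargs)


def load_scenario(path: str | Path) -> ScenarioConfig:
    cfg = ScenarioConfig.from_dict(yaml.safe_load(Path(path).read_text()) or {})
    cfg.validate()
    return cfg


#: A scaled-down emulation of the study cohort: class uptake shares follow the
#: published per-class prevalent/incident user counts relative to the analysed
#: cohort, with modest event hazards and a good/poor refiller mixture.
def default_scenario(n_participants: int = 2000) -> ScenarioConfig:
    return ScenarioConfig(
        n_participants=n_participants,
        classes={
            "metformin": ClassScenario(0.55, 0.15, 0.04, 0.03, {"DPP4i": 0.6, "SGLT2i": 0.4}),
            "sulfonylurea": ClassScenario(0.25, 0.11, 0.03, 0.08, {"DPP4i": 0.7, "SGLT2i": 0.3}),
            "DPP4i": ClassScenario(0.11, 0.21, 0.04, 0.08, {"SGLT2i": 1.0}),
            "TZD": ClassScenario(0.03, 0.005, 0.02, 0.25, {"DPP4i": 0.5, "SGLT2i": 0.5}),
            "GLP1RA": ClassScenario(0.01, 0.06, 0.06, 0.15, {"SGLT2i": 1.0}),
            "SGLT2i": ClassScenario(0.0, 0.19, 0.07, 0.08, {"GLP1RA": 1.0}),
            "insulin": ClassScenario(0.15, 0.08, 0.02, 0.0, {}),
            "acarbose": ClassScenario(0.005, 0.002, 0.1, 0.0, {}),
        },
        theta=ThetaModel(
            kind="mixture",
            components=((0.55, 0.95), (0.30, 0.7), (0.15, 0.45)),
        ),
        p_withdrew=0.01,
        p_no_diabetes=0.05,
        p_died_pre_analysis=0.01,
        p_censor_only_user=0.0,
    )


def _draw_covariates(rng: np.random.Generator, cfg: ScenarioConfig) -> pd.DataFrame:
    n = cfg.n_participants
    sex = np.where(rng.random(n) < cfg.p_female, "female", "male")
    age = np.clip(np.rint(rng.normal(cfg.age_mean, cfg.age_sd, n)), 45, 100).astype(int)
    duration = rng.choice(DURATION_GROUPS, size=n, p=cfg.duration_probs)
    ses = rng.integers(1, 6, size=n)
    remote = rng.choice(REMOTENESS, size=n, p=cfg.remoteness_probs)
    return pd.DataFrame(
        {
            "participant_id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            "age_2013": age,
            "duration_group": duration,
            "ses_quintile": ses,
            "remoteness": remote,
        }
    )


def _age_group_of(age: int) -> str:
    if age < 55:
        return "45-54"
    if age < 65:
        return "55-64"
    if age < 75:
        return "65-74"
    return ">=75"


def _p_good(row: Mapping, tm: ThetaModel) -> float:
    logit = math.log(tm.p_good / (1 - tm.p_good))
    cov_values = {
        "sex": row["sex"],
        "age_group": _age_group_of(row["age_2013"]),
        "duration_group": row["duration_group"],
        "ses_quintile": str(row["ses_quintile"]),
        "remoteness": row["remoteness"],
    }
    for cov, levels in tm.effects.items():
        or_ = levels.get(cov_values.get(cov, ""), 1.0)
        logit += math.log(or_)
    return 1 / (1 + math.exp(-logit))


def _draw_theta(
    rng: np.random.Generator, tm: ThetaModel, row: Mapping
) -> tuple[float, bool | None]:
    if tm.kind == "mixture":
        weights = [w for w, _ in tm.components]
        idx = rng.choice(len(weights), p=weights)
        return tm.components[idx][1], None
    good = rng.random() < _p_good(row, tm)
    return (tm.theta_good if good else tm.theta_poor), bool(good)


def _gen_stream(
    rng: np.random.Generator,
    start: int,
    theta: float,
    scd: int,
    jitter: int,
    hard_end: int,
    stop_after: int | None,
) -> list[int]:
    """Supply-date ordinals: first at ``start``, gaps round(scd/theta)+jitter,
    no supplies after min(hard_end, stop_after)."""
    base = max(1, round(scd / theta))
    limit = hard_end if stop_after is None else min(hard_end, stop_after)
    dates = []
    t = start
    while t <= limit:
        dates.append(t)
        step = base + (int(rng.integers(-jitter, jitter + 1)) if jitter else 0)
        t += max(1, step)
    return dates


def _event_period(rng: np.random.Generator, hazard: float) -> int | None:
    """1-based on-treatment period in which a per-period event fires."""
    if hazard <= 0:
        return None
    # geometric on the period grid; cap well beyond the study horizon
    k = 1
    while k <= 16:
        if rng.random() < hazard:
            return k
        k += 1
    return None


def generate(
    config: ScenarioConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (participants, dispensing, truth) tables.

    Byte-identical outputs for identical (config, seed).  ``truth`` holds one
    row per generated stream with the designed status, theta, good-refiller
    flag and event dates; the pipeline must never read it.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    w = config.window
    study_end = w.study_end.toordinal()
    analysis_start = w.analysis_start.toordinal()
    base_start = w.baseline_start.toordinal()
    base_end = w.baseline_end.toordinal()
    inc_lo, inc_hi = (d.toordinal() for d in config.incident_start)

    part = _draw_covariates(rng, config)
    n = config.n_participants

    withdrew = rng.random(n) < config.p_withdrew
    no_diab = rng.random(n) < config.p_no_diabetes
    died_pre = rng.random(n) < config.p_died_pre_analysis
    censor_only = rng.random(n) < config.p_censor_only_user

    # death process from the analysis start: per-year hazard, day uniform
    death_ord = np.full(n, -1, dtype=int)
    n_years = (study_end - analysis_start) // 365 + 1
    for i in range(n):
        if died_pre[i]:
            death_ord[i] = int(rng.integers(base_start, analysis_start))
            continue
        for y in range(n_years):
            if rng.random() < config.annual_mortality:
                lo = analysis_start + 365 * y
                hi = min(analysis_start + 365 * (y + 1), study_end + 1)
                death_ord[i] = int(rng.integers(lo, hi))
                break

    atc_by_class = {
        "metformin": ("A10BA02", "MET-001"),
        "sulfonylurea": ("A10BB01", "SU-001"),
        "TZD": ("A10BG03", "TZD-001"),
        "DPP4i": ("A10BH01", "DPP4-001"),
        "GLP1RA": ("A10BJ02", "GLP1-001"),
        "SGLT2i": ("A10BK01", "SGLT2-001"),
        "insulin": ("A10AB01", "INS-001"),
        "acarbose": ("A10BF01", "ACA-001"),
    }

    disp_rows: list[tuple[str, int, str, str]] = []
    truth_rows: list[dict] = []

    class_map = ClassMap()

    def run_stream(
        i: int,
        pid: str,
        cls: str,
        status: str,
        start: int,
        theta: float,
        good: bool | None,
        allow_switch: bool,
    ) -> None:
        cs = config.classes[cls]
        scd = class_map.get(cls).scd_days
        death = death_ord[i] if death_ord[i] >= 0 else None
        hard_end = study_end if death is None else min(study_end, death)
        disc_p = _event_period(rng, cs.discontinuation_hazard)
        switch_p = _event_period(rng, cs.switch_hazard) if allow_switch else None
        # competing events on the period grid: death (via hard_end) takes
        # precedence implicitly; discontinuation beats switch in a tie
        event, event_period = None, None
        if disc_p is not None and (switch_p is None or disc_p <= switch_p):
            event, event_period = "discontinuation", disc_p
        elif switch_p is not None:
            event, event_period = "switch", switch_p
        stop_after = None
        if event_period is not None:
            stop_after = start + 365 * (event_period - 1) + int(rng.integers(0, 365))
        dates = _gen_stream(
            rng, start, theta, scd, config.jitter_days, hard_end, stop_after
        )
        atc, item = atc_by_class.get(cls, (f"A10B-{cls}", f"{cls}-001"))
        for d in dates:
            disp_rows.append((pid, d, atc, item))
        stop_date = dates[-1] if dates else start
        switch_to = None
        if event == "switch" and cs.switch_to and stop_after is not None:
            dests, probs = zip(*sorted(cs.switch_to.items()))
            switch_to = str(dests[rng.choice(len(dests), p=np.array(probs))])
        truth_rows.append(
            {
                "participant_id": pid,
                "drug_class": cls,
                "true_status": status,
                "theta": theta,
                "good_refiller": good,
                "start_date": dt.date.fromordinal(start).isoformat(),
                "event": event or "",
                "event_date": (
                    dt.date.fromordinal(stop_after).isoformat()
                    if stop_after is not None and (death is None or stop_after <= death)
                    else ""
                ),
                "switch_to": switch_to or "",
                "death_date": (
                    dt.date.fromordinal(death).isoformat() if death is not None else ""
                ),
            }
        )
        if switch_to is not None and stop_after is not None:
            dest_start = stop_after + int(rng.integers(14, 46))
            if dest_start <= min(study_end, hard_end):
                run_stream(
                    i, pid, switch_to, "incident", dest_start, theta, good, False
                )

    for i in range(n):
        pid = part.loc[i, "participant_id"]
        row = part.loc[i]
        if withdrew[i] or no_diab[i] or died_pre[i]:
            # still emit a plausible record stream so exclusions are exercised
            if rng.random() < 0.5:
                d0 = int(rng.integers(base_start, study_end - 200))
                disp_rows.append((pid, d0, "A10BA02", "MET-001"))
            continue
        if censor_only[i]:
            d0 = int(rng.integers(analysis_start, study_end - 400))
            for k in range(3):
                disp_rows.append((pid, d0 + 30 * k, "A10AB01", "INS-001"))
            continue
        for cls, cs in config.classes.items():
            u = rng.random()
            if u < cs.p_prevalent:
                status = "prevalent"
                start = int(rng.integers(base_start, base_end + 1))
            elif u < cs.p_prevalent + cs.p_incident:
                status = "incident"
                start = int(rng.integers(inc_lo, inc_hi + 1))
            else:
                continue
            theta, good = _draw_theta(rng, config.theta, row)
            run_stream(i, pid, cls, status, start, theta, good, allow_switch=True)

    death_dates = [
        dt.date.fromordinal(o).isoformat() if o >= 0 else "" for o in death_ord
    ]
    participants = part.assign(
        death_date=death_dates,
        withdrew=withdrew.astype(int),
        diabetes=(~no_diab).astype(int),
    )[
        [
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
    ]
    dispensing = pd.DataFrame(
        disp_rows, columns=["participant_id", "date_of_supply", "atc_code", "item_code"]
    ).sort_values(["participant_id", "date_of_supply", "atc_code"], kind="stable")
    dispensing["date_of_supply"] = [
        dt.date.fromordinal(o).isoformat() for o in dispensing["date_of_supply"]
    ]
    truth = pd.DataFrame(truth_rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        participants.to_csv(out / "participants.csv", index=False)
        dispensing.to_csv(out / "dispensing.csv", index=False)
        truth.to_csv(out / "truth.csv", index=False)
    return participants, dispensing.reset_index(drop=True), truth


def simulate_adherence_flags(
    n: int,
    theta_model: ThetaModel,
    seed: int,
    scenario: ScenarioConfig | None = None,
) -> pd.DataFrame:
    """Per-participant covariates with the adherent flag implied by the
    good/poor-refiller truth model.

    Under the two-point design (theta_good above the adherence threshold,
    theta_poor below) the pipeline's adherent flag coincides with the
    good-refiller flag, so regression-recovery studies can run on these rows
    directly.
    """
    if theta_model.kind != "logistic":
        raise ValueError("adherence-flag simulation needs a logistic theta model")
    cfg = dataclasses.replace(scenario or ScenarioConfig(classes={"metformin": ClassScenario(0, 1)}), n_participants=n)
    rng = np.random.default_rng(seed)
    cov = _draw_covariates(rng, cfg)
    p = cov.apply(lambda r: _p_good(r, theta_model), axis=1)
    good = rng.random(n) < p.to_numpy()
    out = cov.assign(
        age_group=[_age_group_of(a) for a in cov["age_2013"]],
        adherent=good,
    )
    return out


# ---------------------------------------------------------------------------
# Worked fixture: a tiny hand-written cohort covering every rule branch.
# ---------------------------------------------------------------------------

def _days(start: str, step: int, count: int) -> list[str]:
    t0 = dt.date.fromisoformat(start).toordinal()
    return [dt.date.fromordinal(t0 + step * k).isoformat() for k in range(count)]


def worked_fixture() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Ten hand-written participants exercising every rule branch.

    F01 prevalent metformin, perfect 5-year refiller; F02 incident poor
    refiller who discontinues; F03 single-record (intolerance flag);
    F04 restart after a >12-month gap; F05 metformin-to-sulfonylurea switch;
    F06 death mid-period-3; F07 gap of exactly 365 days (not a
    discontinuation) then a terminal discontinuation; F08 insulin-only
    (excluded); F09 withdrew; F10 no self-reported diabetes.
    The expected analysis output lives in tests/data and is regenerated by
    an independent day-grid script.
    """
    participants = pd.DataFrame(
        [
            ("F01", "male", 62, "<10y", 3, "major city", "", 0, 1),
            ("F02", "female", 55, "<10y", 1, "inner regional", "", 0, 1),
            ("F03", "male", 71, "10-19y", 2, "major city", "", 0, 1),
            ("F04", "female", 68, "10-19y", 4, "outer regional/remote", "", 0, 1),
            ("F05", "male", 59, "<10y", 5, "major city", "", 0, 1),
            ("F06", "female", 77, ">=20y", 2, "inner regional", "2015-06-30", 0, 1),
            ("F07", "male", 65, "10-19y", 3, "major city", "", 0, 1),
            ("F08", "female", 80, ">=20y", 1, "major city", "", 0, 1),
            ("F09", "male", 58, "<10y", 4, "inner regional", "", 1, 1),
            ("F10", "female", 49, "<10y", 5, "major city", "", 0, 0),
        ],
        columns=[
            "participant_id",
            "sex",
            "age_2013",
            "duration_group",
            "ses_quintile",
            "remoteness",
            "death_date",
            "withdrew",
            "diabetes",
        ],
    )

    met = ("A10BA02", "MET-001")
    su = ("A10BB01", "SU-001")
    ins = ("A10AB01", "INS-001")
    rows: list[tuple[str, str, str, str]] = []

    def add(pid: str, dates: list[str], drug: tuple[str, str]) -> None:
        rows.extend((pid, d, drug[0], drug[1]) for d in dates)

    add("F01", ["2012-10-01"] + _days("2013-01-05", 37, 69), met)
    add("F02", _days("2014-03-01", 74, 8), met)
    add("F03", ["2013-05-10"], met)
    add("F04", ["2013-01-10", "2013-02-16", "2013-03-25", "2014-06-01", "2014-07-08"], met)
    add("F05", ["2013-02-01", "2013-03-10", "2013-04-16"], met)
    add("F05", _days("2013-06-01", 33, 10), su)
    add("F06", ["2012-09-15"] + _days("2013-01-20", 37, 25), met)
    add("F07", ["2013-01-01", "2014-01-01"], met)
    add("F08", _days("2013-03-01", 60, 2), ins)
    add("F09", _days("2013-04-01", 37, 3), met)
    add("F10", _days("2013-04-01", 37, 3), met)

    dispensing = pd.DataFrame(
        rows, columns=["participant_id", "date_of_supply", "atc_code", "item_code"]
    )
    return participants, dispensing
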