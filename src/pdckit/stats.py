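"""Per-period summary tables and subgroup logistic regression.

``summarize_periods`` reproduces the layout of a per-class adherence table:
one row per 12-month period (plus a full-5-years row restricted to
participants continuously on the class), with the share of participants
included for full vs partial analysis (by reason), analysis-day and PDC
moments, and the percentage adherent.

``fit_adherence_model`` fits a multiple logistic regression of the adherent
flag on categorical socio-demographic covariates (maximum likelihood, Wald
95% confidence intervals on the log odds ratio), one model per drug class,
user type, and period.  No multiplicity correction is applied.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .engine import (
    OUTCOME_DIED_OR_END,
    OUTCOME_DISCONTINUED,
    OUTCOME_FULL,
    OUTCOME_SWITCHED,
    categorize_pdc,
)

# reference levels: male, youngest age group, shortest duration, most
# disadvantaged quintile, major cities
DEFAULT_COVARIATES: tuple[tuple[str, str], ...] = (
    ("sex", "male"),
    ("age_group", "45-54"),
    ("duration_group", "<10y"),
    ("ses_quintile", "1"),
    ("remoteness", "major city"),
)

DEFAULT_AGE_BINS: tuple[int, ...] = (45, 55, 65, 75)


def age_group(age: pd.Series, bins: Sequence[int] = DEFAULT_AGE_BINS) -> pd.Series:
    """Categorise age in years into the study's age groups
    (default 45-54, 55-64, 65-74, >=75)."""
    edges = list(bins) + [np.inf]
    labels = [
        f"{lo}-{hi - 1}" if np.isfinite(hi) else f">={lo}"
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return pd.cut(age, bins=edges, labels=labels, right=False).astype(str)


def _iqr_text(s: pd.Series) -> str:
    if s.empty:
        return ""
    q1, q3 = s.quantile([0.25, 0.75])
    return f"{q1:.2f}-{q3:.2f}"


def summarize_periods(
    period_results: pd.DataFrame,
    five_year: pd.DataFrame,
    user_status: pd.DataFrame,
    class_name: str,
    user_type: str,
    max_periods: int = 5,
) -> pd.DataFrame:
    """One summary row per period 1..max_periods plus a full-5-years row.

    Percentages are over included participants in that period; a period with
    n=0 yields a row with null statistics.
    """
    ids = user_status.loc[
        (user_status["drug_class"] == class_name)
        & (user_status["user_status"] == user_type),
        "participant_id",
    ]
    pr = period_results[
        (period_results["drug_class"] == class_name)
        & period_results["participant_id"].isin(set(ids))
    ]
    fy = five_year[
        (five_year["drug_class"] == class_name)
        & five_year["participant_id"].isin(set(ids))
    ]

    rows = []
    for k in range(1, max_periods + 1):
        sub = pr[pr["period_index"] == k]
        n = len(sub)
        row = {
            "class_name": class_name,
            "user_type": user_type,
            "period": str(k),
            "n": n,
        }
        if n == 0:
            row.update(
                {c: np.nan for c in (
                    "pct_full", "pct_partial_death_or_end",
                    "pct_partial_discontinued", "pct_partial_switched",
                    "mean_analysis_days", "sd_analysis_days",
                    "mean_pdc", "sd_pdc", "median_pdc", "pct_adherent",
                )}
            )
            row["iqr_pdc"] = ""
        else:
            oc = sub["outcome"].value_counts()
            row.update(
                {
                    "pct_full": 100 * oc.get(OUTCOME_FULL, 0) / n,
                    "pct_partial_death_or_end": 100 * oc.get(OUTCOME_DIED_OR_END, 0) / n,
                    "pct_partial_discontinued": 100 * oc.get(OUTCOME_DISCONTINUED, 0) / n,
                    "pct_partial_switched": 100 * oc.get(OUTCOME_SWITCHED, 0) / n,
                    "mean_analysis_days": sub["analysis_days"].mean(),
                    "sd_analysis_days": sub["analysis_days"].std(ddof=1),
                    "mean_pdc": sub["pdc"].mean(),
                    "sd_pdc": sub["pdc"].std(ddof=1),
                    "median_pdc": sub["pdc"].median(),
                    "iqr_pdc": _iqr_text(sub["pdc"]),
                    "pct_adherent": 100 * sub["adherent"].mean(),
                }
            )
        rows.append(row)

    n5 = len(fy)
    row5 = {
        "class_name": class_name,
        "user_type": user_type,
        "period": "full_5y",
        "n": n5,
    }
    if n5 == 0:
        row5.update(
            {c: np.nan for c in (
                "pct_full", "pct_partial_death_or_end", "pct_partial_discontinued",
                "pct_partial_switched", "mean_analysis_days", "sd_analysis_days",
                "mean_pdc", "sd_pdc", "median_pdc", "pct_adherent",
            )}
        )
        row5["iqr_pdc"] = ""
    else:
        row5.update(
            {
                "pct_full": 100.0,
                "pct_partial_death_or_end": 0.0,
                "pct_partial_discontinued": 0.0,
                "pct_partial_switched": 0.0,
                "mean_analysis_days": fy["analysis_days"].mean(),
                "sd_analysis_days": fy["analysis_days"].std(ddof=1),
                "mean_pdc": fy["pdc_5y"].mean(),
                "sd_pdc": fy["pdc_5y"].std(ddof=1),
                "median_pdc": fy["pdc_5y"].median(),
                "iqr_pdc": _iqr_text(fy["pdc_5y"]),
                "pct_adherent": 100 * fy["adherent_5y"].mean(),
            }
        )
    rows.append(row5)
    return pd.DataFrame(rows)


_TERM_RE = re.compile(r"C\((?P<cov>\w+),.*\)\[T\.(?P<level>[^\]]+)\]$")


def fit_adherence_model(
    rows: pd.DataFrame,
    covariates: Sequence[tuple[str, str]] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Adjusted logistic regression of ``adherent`` on categorical covariates.

    Returns tidy rows (covariate, level, odds_ratio, ci_low, ci_high,
    reference_level, note); reference levels appear with OR 1.  Covariates
    with an absent reference level fall back to the modal level; covariates
    causing complete separation are dropped, both with a recorded note.
    """
    df = rows.copy()
    if df["adherent"].nunique() < 2:
        raise ValueError("need both adherent and non-adherent rows to fit")
    notes: dict[str, str] = {}
    active: list[tuple[str, str]] = []
    for cov, ref in covariates:
        levels = df[cov].astype(str)
        df[cov] = levels
        observed = levels.unique()
        if len(observed) < 2:
            notes[cov] = f"dropped: single level {observed[0]!r}"
            continue
        if ref not in observed:
            new_ref = levels.mode().iloc[0]
            notes[cov] = f"reference {ref!r} absent; using {new_ref!r}"
            ref = new_ref
        active.append((cov, ref))

    def formula(terms: Sequence[tuple[str, str]]) -> str:
        parts = [f"C({c}, Treatment('{r}'))" for c, r in terms]
        return "adherent_int ~ " + " + ".join(parts)

    df["adherent_int"] = df["adherent"].astype(int)
    terms = list(active)
    fit = None
    while terms:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.logit(formula(terms), data=df)
                fit = model.fit(disp=0, maxiter=100)
            if np.isfinite(fit.bse).all() and (fit.bse < 50).all():
                break
            raise sm.tools.sm_exceptions.PerfectSeparationError("huge SEs")
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            np.linalg.LinAlgError,
        ):
            dropped_cov, _ = terms.pop()  # drop last covariate and refit
            notes[dropped_cov] = "dropped: complete separation"
            warnings.warn(
                f"dropping covariate {dropped_cov!r} (separation)", stacklevel=2
            )
            fit = None
    if fit is None:
        raise ValueError("no covariate could be fitted (complete separation)")

    params = fit.params
    ci = fit.conf_int()
    out = []
    for cov, ref in terms:
        out.append(
            {
                "covariate": cov,
                "level": ref,
                "odds_ratio": 1.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "reference_level": ref,
                "note": notes.get(cov, ""),
            }
        )
        for name, beta in params.items():
            m = _TERM_RE.match(name)
            if m and m.group("cov") == cov:
                lo, hi = ci.loc[name]
                out.append(
                    {
                        "covariate": cov,
                        "level": m.group("level"),
                        "odds_ratio": float(np.exp(beta)),
                        "ci_low": float(np.exp(lo)),
                        "ci_high": float(np.exp(hi)),
                        "reference_level": ref,
                        "note": notes.get(cov, ""),
                    }
                )
    for cov, note in notes.items():
        if cov not in [c for c, _ in terms]:
            out.append(
                {
                    "covariate": cov,
                    "level": "",
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "reference_level": "",
                    "note": note,
                }
            )
    return pd.DataFrame(out)


def categorize_levels(
    pdc: pd.Series,
    by: pd.DataFrame | None = None,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Distribution over adherence levels {<0.5, 0.5-<0.8, >=0.8}.

    With ``by`` (a frame of grouping columns aligned to ``pdc``), one row of
    shares per group; shares sum to 1 within each row.
    """
    cats = pd.Series(
        [categorize_pdc(v, threshold) for v in pdc], index=pdc.index, name="category"
    )
    order = ["strongly_nonadherent", "nonadherent", "adherent"]
    if by is None:
        shares = cats.value_counts(normalize=True).reindex(order, fill_value=0.0)
        return shares.rename_axis("category").rename("share").reset_index()
    frame = pd.concat([by.reset_index(drop=True), cats.reset_index(drop=True)], axis=1)
    tab = (
        frame.groupby(list(by.columns))["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=order, fill_value=0.0)
    )
    return tab.reset_index()
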