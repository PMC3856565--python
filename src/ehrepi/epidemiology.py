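"""Person-time denominators, annual incidence and mid-year point prevalence.

Denominator construction follows registry convention: each patient
contributes at-risk days to every calendar year from registration start to
the earliest of death, transfer-out and the last collection date, censored
additionally at their ADHD presentation date (the presentation day itself
is not at risk). Days are converted to person-years with divisor 365.25;
leap days are counted literally. Patients who never meet the case criteria
contribute person-time in full.

Age is attributed by the band attained on 1 July of the calendar year
(with the imputed 1 July birthday this is simply ``year - birth_year``),
applied to the whole year's days, for numerators and denominators alike.

Point prevalence on 1 July of a year counts patients whose presentation
precedes the mid-year point and whose last ADHD record (diagnosis or
prescription, whichever is later) falls after it, over everyone registered
on that date. Years closer than 12 months to the last collection date are
refused: the chance of observing a post-mid-year record shrinks as the
collection horizon approaches, which would bias prevalence downward.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .config import AGE_BANDS, CohortDefinition, age_band

DAYS_PER_YEAR = 365.25

LEDGER_COLUMNS = ["patient_id", "year", "sex", "age_band", "days"]


class WashoutError(ValueError):
    """Prevalence requested for a year too close to the collection horizon."""


class InconsistentDenominatorError(ValueError):
    """Events observed in a stratum with zero person-time."""


@dataclass
class RateEstimate:
    year: int
    age_band: str  # one of AGE_BANDS or "all"
    sex: str  # "M", "F" or "all"
    numerator: int
    person_years: float
    rate_per_100k: float
    pct_change_vs_ref: Optional[int] = None


@dataclass
class PrevalenceEstimate:
    year: int
    age_band: str
    sex: str
    prevalent_count: int
    registered_count: int
    prevalence_per_100k: float
    pct_change_vs_ref: Optional[int] = None


def build_person_time_ledger(
    patients: pd.DataFrame,
    cases: pd.DataFrame,
    year_min: int,
    year_max: int,
) -> pd.DataFrame:
    """At-risk days per (patient, calendar year) with mid-year age banding.

    ``cases`` needs ``patient_id`` and ``index_date``; everyone else is
    uncensored by presentation. Rows with zero days are dropped.
    """
    if patients.empty:
        return pd.DataFrame(columns=LEDGER_COLUMNS)
    idx_map = (
        cases.set_index("patient_id")["index_date"].map(dt.date.toordinal)
        if len(cases)
        else pd.Series(dtype=np.int64)
    )
    start = patients["registration_start"].map(dt.date.toordinal).to_numpy(np.int64)
    end = patients["registration_end"].map(dt.date.toordinal).to_numpy(np.int64)
    present = patients["patient_id"].map(idx_map).to_numpy(dtype=float)
    # censor the day before presentation; non-cases keep registration end
    cap = np.where(np.isnan(present), end, np.fmin(end, present - 1)).astype(np.int64)

    rows = []
    for year in range(year_min, year_max + 1):
        y_start = dt.date(year, 1, 1).toordinal()
        y_end = dt.date(year, 12, 31).toordinal()
        a = np.maximum(start, y_start)
        b = np.minimum(cap, y_end)
        days = b - a + 1
        live = days > 0
        if not live.any():
            continue
        age = year - patients["birth_year"].to_numpy()[live]
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": patients["patient_id"].to_numpy()[live],
                    "year": year,
                    "sex": patients["sex"].to_numpy()[live],
                    "age_band": [age_band(max(int(x), 0)) for x in age],
                    "days": days[live],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=LEDGER_COLUMNS)
    return pd.concat(rows, ignore_index=True)


def _stratum_mask(df: pd.DataFrame, band: str, sex: str) -> pd.Series:
    mask = pd.Series(True, index=df.index)
    if band != "all":
        mask &= df["age_band"] == band
    if sex != "all":
        mask &= df["sex"] == sex
    return mask


def person_years_at_risk(
    ledger: pd.DataFrame, year: int, band: str = "all", sex: str = "all"
) -> float:
    """Sum at-risk days in the (year, stratum) cell, in years (/365.25)."""
    if ledger.empty:
        return 0.0
    sel = ledger[(ledger["year"] == year) & _stratum_mask(ledger, band, sex)]
    return float(sel["days"].sum()) / DAYS_PER_YEAR


def _case_stratum(cases: pd.DataFrame, year: int) -> pd.DataFrame:
    """Annotated copy of ``cases`` with mid-year age band for ``year``.

    Requires ``birth_year`` and ``sex`` columns (see
    :func:`annotate_cases`).
    """
    for col in ("birth_year", "sex"):
        if col not in cases.columns:
            raise KeyError(f"cases must carry {col!r}; use annotate_cases()")
    out = cases.copy()
    out["age_band"] = [age_band(max(year - by, 0)) for by in out["birth_year"]]
    return out


def annotate_cases(cases: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Attach sex and birth year (needed for stratified rates) to case rows."""
    return cases.merge(
        patients[["patient_id", "sex", "birth_year", "practice_id"]],
        on="patient_id",
        how="left",
    )


def annual_incidence(
    cases: pd.DataFrame,
    ledger: pd.DataFrame,
    year: int,
    band: str = "all",
    sex: str = "all",
    rate_ref: Optional[float] = None,
) -> RateEstimate:
    """New presentations in ``year`` over person-years at risk, per 100,000."""
    py = person_years_at_risk(ledger, year, band, sex)
    if cases.empty:
        num = 0
    else:
        annotated = _case_stratum(cases, year)
        in_year = annotated["index_date"].map(lambda d: d.year) == year
        num = int((in_year & _stratum_mask(annotated, band, sex)).sum())
    if num > 0 and py <= 0:
        raise InconsistentDenominatorError(
            f"{num} cases in {year}/{band}/{sex} but zero person-years"
        )
    rate = 0.0 if py == 0 else num / py * 1e5
    pct = percent_change(rate_ref, rate) if rate_ref else None
    return RateEstimate(year, band, sex, num, py, rate, pct)


def treated_incidence(
    prescriptions: pd.DataFrame,
    ledger: pd.DataFrame,
    patients: pd.DataFrame,
    defn: CohortDefinition,
    year: int,
    band: str = "all",
    sex: str = "all",
    rate_ref: Optional[float] = None,
) -> RateEstimate:
    """First-ever ADHD drug prescription as the incident event."""
    rx = prescriptions[prescriptions["product"].isin(defn.adhd_drug_set)]
    first = rx.groupby("patient_id", as_index=False)["date"].min()
    first = first.rename(columns={"date": "index_date"})
    first = annotate_cases(first, patients)
    py = person_years_at_risk(ledger, year, band, sex)
    if first.empty:
        num = 0
    else:
        annotated = _case_stratum(first, year)
        in_year = annotated["index_date"].map(lambda d: d.year) == year
        num = int((in_year & _stratum_mask(annotated, band, sex)).sum())
    if num > 0 and py <= 0:
        raise InconsistentDenominatorError(
            f"{num} first prescriptions in {year}/{band}/{sex} but zero person-years"
        )
    rate = 0.0 if py == 0 else num / py * 1e5
    pct = percent_change(rate_ref, rate) if rate_ref else None
    return RateEstimate(year, band, sex, num, py, rate, pct)


def point_prevalence(
    patients: pd.DataFrame,
    cases: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    defn: CohortDefinition,
    year: int,
    db_last_collection: dt.date,
    band: str = "all",
    sex: str = "all",
    rate_ref: Optional[float] = None,
) -> PrevalenceEstimate:
    """Mid-year (1 July) point prevalence per 100,000 registered patients.

    A case counts as prevalent if their presentation date is strictly
    before 1 July and the later of their last ADHD diagnosis and last ADHD
    prescription is strictly after 1 July, and they are registered on that
    date. Raises :class:`WashoutError` when fewer than 12 months separate
    1 July from the last collection date.
    """
    mid = dt.date(year, 7, 1)
    if (db_last_collection - mid).days <= 365:
        raise WashoutError(
            f"prevalence for {year} refused: less than 12 months between "
            f"{mid} and last collection {db_last_collection}"
        )
    registered = patients[
        (patients["registration_start"] <= mid) & (patients["registration_end"] >= mid)
    ].copy()
    registered["age_band"] = [
        age_band(max(year - by, 0)) for by in registered["birth_year"]
    ]
    denom_df = registered[_stratum_mask(registered, band, sex)]
    denom = len(denom_df)

    if cases.empty or denom == 0:
        prev_count = 0
    else:
        dx = diagnoses[diagnoses["code"].isin(defn.adhd_code_set)]
        rx = prescriptions[prescriptions["product"].isin(defn.adhd_drug_set)]
        last_dx = dx.groupby("patient_id")["date"].max().to_dict()
        last_rx = rx.groupby("patient_id")["date"].max().to_dict()
        denom_ids = set(denom_df["patient_id"])
        prev_count = 0
        for rec in cases.itertuples(index=False):
            if rec.patient_id not in denom_ids:
                continue
            if rec.index_date >= mid:
                continue
            last = max(
                (d for d in (last_dx.get(rec.patient_id), last_rx.get(rec.patient_id))
                 if d is not None),
                default=None,
            )
            if last is not None and last > mid:
                prev_count += 1

    prevalence = 0.0 if denom == 0 else prev_count / denom * 1e5
    pct = percent_change(rate_ref, prevalence) if rate_ref else None
    return PrevalenceEstimate(year, band, sex, prev_count, denom, prevalence, pct)


def percent_change(rate_ref: float, rate_t: float) -> int:
    """Percent change vs the reference rate, rounded to the nearest integer
    (half away from zero, matching conventional display rounding)."""
    if rate_ref is None or rate_ref <= 0:
        raise ValueError("percent change undefined for non-positive reference rate")
    raw = (rate_t - rate_ref) / rate_ref * 100.0
    return int(np.floor(raw + 0.5)) if raw >= 0 else -int(np.floor(-raw + 0.5))


def incidence_series(
    cases: pd.DataFrame,
    ledger: pd.DataFrame,
    years: list[int],
    strata: Optional[list[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Tidy table of annual incidence across years and strata.

    Percent change is reported against the first year in ``years`` (the
    study's reference year), left missing where the reference rate is zero.
    """
    strata = strata or [(b, s) for b in ("all", *AGE_BANDS) for s in ("all", "M", "F")]
    rows = []
    for band, sex in strata:
        ref = annual_incidence(cases, ledger, years[0], band, sex)
        for year in years:
            est = annual_incidence(
                cases, ledger, year, band, sex,
                rate_ref=ref.rate_per_100k if ref.rate_per_100k > 0 else None,
            )
            rows.append(est)
    return rates_frame(rows)


def prevalence_series(
    patients: pd.DataFrame,
    cases: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    defn: CohortDefinition,
    years: list[int],
    db_last_collection: dt.date,
    strata: Optional[list[tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Tidy prevalence table; washout-refused years appear as not-computed
    rows (missing counts), which downstream rendering keeps distinct from
    zero."""
    strata = strata or [(b, s) for b in ("all", *AGE_BANDS) for s in ("all", "M", "F")]
    rows = []
    for band, sex in strata:
        ref_val: Optional[float] = None
        for year in years:
            try:
                est = point_prevalence(
                    patients, cases, diagnoses, prescriptions, defn, year,
                    db_last_collection, band, sex, rate_ref=ref_val,
                )
            except WashoutError:
                rows.append(
                    {"year": year, "age_band": band, "sex": sex,
                     "prevalent_count": pd.NA, "registered_count": pd.NA,
                     "prevalence_per_100k": pd.NA, "pct_change_vs_ref": pd.NA,
                     "computed": False}
                )
                continue
            if ref_val is None and est.prevalence_per_100k > 0:
                ref_val = est.prevalence_per_100k
            rows.append(
                {"year": est.year, "age_band": est.age_band, "sex": est.sex,
                 "prevalent_count": est.prevalent_count,
                 "registered_count": est.registered_count,
                 "prevalence_per_100k": round(est.prevalence_per_100k, 1),
                 "pct_change_vs_ref": est.pct_change_vs_ref, "computed": True}
            )
    return pd.DataFrame(rows)


def rates_frame(estimates: list[RateEstimate]) -> pd.DataFrame:
    """Rate estimates as a tidy frame, rates rounded to 1 dp for display."""
    return pd.DataFrame(
        [
            {
                "year": e.year,
                "age_band": e.age_band,
                "sex": e.sex,
                "numerator": e.numerator,
                "person_years": round(e.person_years, 2),
                "rate_per_100k": round(e.rate_per_100k, 1),
                "pct_change_vs_ref": e.pct_change_vs_ref,
            }
            for e in estimates
        ]
    )
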