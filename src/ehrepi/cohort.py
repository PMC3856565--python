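"""Case ascertainment, exclusions and matched-control selection.

A patient qualifies as a diagnosed-ADHD case through one of two routes:
at least two ADHD diagnosis codes at any time, or at least one diagnosis
plus at least one prescription for an ADHD drug (dexamfetamine,
methylphenidate or atomoxetine). The two-diagnosis requirement guards
against counting a single provisional GP diagnosis. The index date —
"ADHD presentation" — is the earlier of the first ADHD diagnosis and the
first ADHD prescription.

Cases are excluded for any-time narcolepsy history, or for less than the
configured wash-in of registered time before the index date (six months,
fixed at 182 days, boundary inclusive). Controls are sampled uniformly
without replacement from patients with no ADHD diagnosis and no ADHD
prescription, exactly matched on (birth year, sex, practice), and inherit
the matched case's index date as a pseudo-index for the costing windows.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CohortDefinition, age_band

CASE_COLUMNS = [
    "patient_id", "index_date", "qualifying_route", "age_at_index", "age_group",
]
CONTROL_COLUMNS = ["patient_id", "case_patient_id", "pseudo_index_date"]
EXCLUSION_COLUMNS = ["patient_id", "reason"]


@dataclass
class CohortResult:
    """Retained cases, matched controls and the exclusion log."""

    cases: pd.DataFrame
    controls: pd.DataFrame
    exclusions: pd.DataFrame
    #: cases that received fewer controls than requested: patient_id -> n found
    shortfall: dict[int, int] = field(default_factory=dict)


def imputed_birthdate(birth_year: int) -> dt.date:
    """Mid-year imputation: only birth year is recorded, 1 July is assumed."""
    return dt.date(int(birth_year), 7, 1)


def age_at(birth_year: int, date: dt.date) -> int:
    """Completed years of age on ``date`` against the imputed birthdate."""
    dob = imputed_birthdate(birth_year)
    if date < dob:
        raise ValueError(f"date {date} precedes imputed birthdate {dob}")
    age = date.year - dob.year
    if (date.month, date.day) < (dob.month, dob.day):
        age -= 1
    return age


def age_group_at(birth_year: int, date: dt.date) -> str:
    """Age band (0-5, 6-17, >=18) attained on ``date``."""
    return age_band(age_at(birth_year, date))


def select_cases(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    defn: CohortDefinition,
) -> pd.DataFrame:
    """Apply the two qualifying routes and assign index dates.

    Returns one row per case with the qualifying route, the index date and
    the age band attained at index. A single diagnosis with no qualifying
    prescription does not make a case.
    """
    dx = diagnoses[diagnoses["code"].isin(defn.adhd_code_set)]
    rx = prescriptions[prescriptions["product"].isin(defn.adhd_drug_set)]

    dx_stats = dx.groupby("patient_id")["date"].agg(n="size", first="min")
    rx_first = rx.groupby("patient_id")["date"].min().to_dict()

    rows = []
    for pid, rec in dx_stats.iterrows():
        n_dx, first_dx = rec["n"], rec["first"]
        first_rx = rx_first.get(pid)
        if n_dx >= 2:
            route = "two_diagnoses"
        elif first_rx is not None:
            route = "diagnosis_plus_prescription"
        else:
            continue
        index_date = first_dx if first_rx is None else min(first_dx, first_rx)
        rows.append((pid, index_date, route))

    if not rows:
        return pd.DataFrame(columns=CASE_COLUMNS)
    cases = pd.DataFrame(rows, columns=["patient_id", "index_date", "qualifying_route"])
    cases = cases.merge(patients[["patient_id", "birth_year"]], on="patient_id")
    cases["age_at_index"] = [
        age_at(by, d) for by, d in zip(cases["birth_year"], cases["index_date"])
    ]
    cases["age_group"] = cases["age_at_index"].map(age_band)
    return cases.drop(columns="birth_year").sort_values("patient_id").reset_index(drop=True)[
        CASE_COLUMNS
    ]


def apply_exclusions(
    cases: pd.DataFrame,
    diagnoses: pd.DataFrame,
    patients: pd.DataFrame,
    defn: CohortDefinition,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop narcolepsy-history and short-wash-in cases.

    Narcolepsy history counts at any time, before or after index. Wash-in
    requires at least ``defn.washin_days`` days of registration strictly
    before the index date; exactly the threshold is retained. Narcolepsy is
    checked first so each excluded case logs a single deterministic reason.
    """
    narc_ids = set(
        diagnoses.loc[diagnoses["code"].isin(defn.exclusion_code_set), "patient_id"]
    )
    reg_start = patients.set_index("patient_id")["registration_start"]

    excl_rows = []
    keep = []
    for rec in cases.itertuples(index=False):
        if rec.patient_id in narc_ids:
            excl_rows.append((rec.patient_id, "narcolepsy"))
            continue
        washin = (rec.index_date - reg_start[rec.patient_id]).days
        if washin < defn.washin_days:
            excl_rows.append((rec.patient_id, "wash_in"))
            continue
        keep.append(rec.patient_id)

    retained = cases[cases["patient_id"].isin(keep)].reset_index(drop=True)
    log = pd.DataFrame(excl_rows, columns=EXCLUSION_COLUMNS)
    return retained, log


def match_controls(
    cases: pd.DataFrame,
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    defn: CohortDefinition,
    seed: int,
) -> CohortResult:
    """Sample up to ``defn.control_ratio`` controls per case.

    Candidates must have no ADHD diagnosis code and no ADHD drug
    prescription at any time. Sampling is uniform without replacement
    within the exact (birth_year, sex, practice_id) cell, shared across the
    cases of a cell, and deterministic under ``seed``. Cases whose cell runs
    dry keep whatever controls exist and are recorded in ``shortfall``.
    """
    rng = np.random.default_rng(seed)
    with_dx = set(diagnoses.loc[diagnoses["code"].isin(defn.adhd_code_set), "patient_id"])
    with_rx = set(
        prescriptions.loc[prescriptions["product"].isin(defn.adhd_drug_set), "patient_id"]
    )
    case_ids = set(cases["patient_id"])
    ineligible = with_dx | with_rx | case_ids

    pat = patients.set_index("patient_id")
    pool: dict[tuple[int, str, int], list[int]] = {}
    for rec in patients.itertuples(index=False):
        if rec.patient_id in ineligible:
            continue
        pool.setdefault((rec.birth_year, rec.sex, rec.practice_id), []).append(rec.patient_id)

    control_rows = []
    shortfall: dict[int, int] = {}
    exclusions_append = []
    for rec in cases.sort_values("patient_id").itertuples(index=False):
        key = (
            int(pat.at[rec.patient_id, "birth_year"]),
            pat.at[rec.patient_id, "sex"],
            int(pat.at[rec.patient_id, "practice_id"]),
        )
        cell = pool.get(key, [])
        k = min(defn.control_ratio, len(cell))
        if k < defn.control_ratio:
            shortfall[int(rec.patient_id)] = k
        if k:
            picks = rng.choice(len(cell), size=k, replace=False)
            chosen = [cell[i] for i in sorted(picks)]
            for cid in chosen:
                control_rows.append((cid, rec.patient_id, rec.index_date))
            pool[key] = [c for c in cell if c not in set(chosen)]

    controls = pd.DataFrame(control_rows, columns=CONTROL_COLUMNS)
    exclusions = pd.DataFrame(exclusions_append, columns=EXCLUSION_COLUMNS)
    return CohortResult(
        cases=cases.reset_index(drop=True),
        controls=controls,
        exclusions=exclusions,
        shortfall=shortfall,
    )


def build_cohort(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    defn: CohortDefinition,
    seed: int,
) -> CohortResult:
    """Convenience wrapper: select, exclude, then match, in one call."""
    cases = select_cases(patients, diagnoses, prescriptions, defn)
    retained, log = apply_exclusions(cases, diagnoses, patients, defn)
    result = match_controls(retained, patients, diagnoses, prescriptions, defn, seed)
    result.exclusions = pd.concat([log, result.exclusions], ignore_index=True)
    return result
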