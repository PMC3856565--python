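"""Unit-cost attribution across the five resource categories and the
per-patient annual cost/resource summaries.

Categories are: investigations, primary-care consultations, prescriptions,
outpatient attendances and hospital admissions. Prescription items get a
net ingredient cost with a four-level fallback (exact product, BNF
sub-paragraph average, section average, chapter average) and are inflated
to 2011 prices; other tariffs are used as published in their schedules.
Same-day laboratory tests are grouped into defined panels (greedy, largest
panel first) to reflect the reduced cost of batched testing; ambiguous
day-case admissions are priced at the elective/emergency mix, and every
admission carries the fixed procedural uplift (17.5% by default)
compensating for missing procedure detail.

Annual windows are 365-day blocks after the index date: follow-up year k
covers days 365(k-1)+1 .. 365k. A patient enters the year-k summary only
if their observation extends through day 365k (complete-year rule).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import CATEGORIES
from .schedules import CostSchedule

YEAR_DAYS = 365
STAT_NAMES = ("mean", "sd", "median", "p25", "p75")


class UnpriceableEventError(ValueError):
    """No tariff could be attributed to an event at any fallback level."""


@dataclass
class CostedEvent:
    patient_id: int
    date: dt.date
    category: str
    cost: float
    attribution_level: str = "n/a"  # exact | sub_paragraph | section | chapter | n/a


@dataclass
class AnnualCostSummary:
    group: str  # case | control
    age_band: str
    followup_year: int
    n: int
    #: category (or "total") -> {mean, sd, median, p25, p75}; None when n == 0
    stats: Optional[dict[str, dict[str, float]]]


@dataclass
class CostingReport:
    """Run accounting for lenient mode and fallback logging."""

    n_costed: int = 0
    n_skipped: int = 0
    skipped: list[str] = field(default_factory=list)
    n_default_outpatient: int = 0
    n_zero_duration: int = 0


# --------------------------------------------------------------------------
# per-event attribution
# --------------------------------------------------------------------------

BNF_LADDER_LEVELS = ("sub_paragraph", "section", "chapter")


def _bnf_key(bnf_code: str, level: str) -> Optional[str]:
    parts = bnf_code.split(".")
    depth = {"sub_paragraph": 3, "section": 2, "chapter": 1}[level]
    if len(parts) < depth:
        return None
    return ".".join(parts[:depth])


def _bnf_ladder(bnf_code: str) -> list[tuple[str, str]]:
    parts = bnf_code.split(".")
    ladder = []
    if len(parts) >= 3:
        ladder.append(("sub_paragraph", ".".join(parts[:3])))
    if len(parts) >= 2:
        ladder.append(("section", ".".join(parts[:2])))
    ladder.append(("chapter", parts[0]))
    return ladder


def cost_prescription(prescription, schedule: CostSchedule) -> CostedEvent:
    """NIC lookup with BNF fallback, inflated to 2011 prices.

    ``prescription`` needs attributes ``patient_id``, ``date``, ``product``
    and ``bnf_code`` (a namedtuple row works).
    """
    year = prescription.date.year
    factor = schedule.inflation_index.get(year, 1.0)
    nic = schedule.drug_nic.get((prescription.product, year))
    if nic is not None:
        return CostedEvent(prescription.patient_id, prescription.date,
                           "prescriptions", nic * factor, "exact")
    for level, key in _bnf_ladder(str(prescription.bnf_code)):
        avg = schedule.bnf_averages.get((level, key, year))
        if avg is not None:
            return CostedEvent(prescription.patient_id, prescription.date,
                               "prescriptions", avg * factor, level)
    raise UnpriceableEventError(
        f"no NIC at any BNF level for product={prescription.product!r} "
        f"bnf_code={prescription.bnf_code!r} year={year}"
    )


def cost_consultation(
    consultation, schedule: CostSchedule, report: Optional[CostingReport] = None
) -> CostedEvent:
    """Primary-care contact priced per visit, or per hour x average duration."""
    key = (consultation.consultation_type, consultation.staff_type)
    if key not in schedule.consultation_costs:
        raise UnpriceableEventError(f"no consultation cost for {key!r}")
    unit, cost = schedule.consultation_costs[key]
    if unit == "per_visit":
        value = cost
    elif unit == "per_hour":
        minutes = schedule.duration_minutes.get(consultation.consultation_type, 0.0)
        if minutes <= 0 and report is not None:
            report.n_zero_duration += 1
        value = cost * minutes / 60.0
    else:
        raise UnpriceableEventError(f"unknown cost unit {unit!r} for {key!r}")
    return CostedEvent(consultation.patient_id, consultation.date,
                       "primary_care", value, "n/a")


def group_tests_into_panels(
    codes: list[str], schedule: CostSchedule
) -> tuple[float, list[str]]:
    """Greedy panel grouping of one day's tests; returns (total, components).

    Largest defined panel first (ties broken by panel id); each application
    consumes one instance of each member test; leftovers are priced
    individually. Raises for a test code absent from the tariff table.
    """
    remaining = list(codes)
    components: list[str] = []
    total = 0.0
    panels = sorted(schedule.panels, key=lambda p: (-len(p.tests), p.panel_id))
    applied = True
    while applied:
        applied = False
        for panel in panels:
            if all(remaining.count(t) >= 1 for t in panel.tests):
                for t in panel.tests:
                    remaining.remove(t)
                total += panel.tariff
                components.append(panel.panel_id)
                applied = True
                break
    for code in remaining:
        if code not in schedule.investigation_tariffs:
            raise UnpriceableEventError(f"no tariff for test code {code!r}")
        total += schedule.investigation_tariffs[code]
        components.append(code)
    return total, components


def cost_investigations(tests_on_one_day: pd.DataFrame, schedule: CostSchedule) -> CostedEvent:
    """One costed event for all of a patient's same-day laboratory tests."""
    if tests_on_one_day.empty:
        raise ValueError("empty test day")
    pids = tests_on_one_day["patient_id"].unique()
    dates = tests_on_one_day["date"].unique()
    if len(pids) != 1 or len(dates) != 1:
        raise ValueError("tests_on_one_day must share one patient and one date")
    total, _ = group_tests_into_panels(list(tests_on_one_day["test_code"]), schedule)
    return CostedEvent(int(pids[0]), dates[0], "investigations", total, "n/a")


def cost_outpatient(
    appointment, schedule: CostSchedule, report: Optional[CostingReport] = None
) -> CostedEvent:
    """Outpatient tariff by (department, first vs follow-up), with a logged
    default tariff for unknown departments."""
    key = (appointment.department, appointment.visit_order)
    tariff = schedule.outpatient_tariffs.get(key)
    if tariff is None:
        tariff = schedule.default_outpatient_tariff
        if report is not None:
            report.n_default_outpatient += 1
    return CostedEvent(appointment.patient_id, appointment.date,
                       "outpatient", tariff, "n/a")


def cost_admission(admission, schedule: CostSchedule) -> CostedEvent:
    """Admission tariff by casemix group, mix-averaged for ambiguous day
    cases, with the procedural uplift applied."""
    group = admission.group_code
    atype = admission.admission_type
    if atype == "daycase_ambiguous":
        elective = schedule.admission_tariffs.get((group, "elective"))
        emergency = schedule.admission_tariffs.get((group, "emergency"))
        if elective is None or emergency is None:
            raise UnpriceableEventError(f"no tariff pair for group {group!r}")
        share = schedule.daycase_elective_share
        base = share * elective + (1.0 - share) * emergency
    else:
        base = schedule.admission_tariffs.get((group, atype))
        if base is None:
            raise UnpriceableEventError(f"no tariff for ({group!r}, {atype!r})")
    return CostedEvent(admission.patient_id, admission.date, "admissions",
                       base * (1.0 + schedule.procedural_uplift), "n/a")


# --------------------------------------------------------------------------
# batch costing
# --------------------------------------------------------------------------

def cost_events(
    dataset,
    schedule: CostSchedule,
    strict: bool = True,
) -> tuple[pd.DataFrame, CostingReport]:
    """Cost every event in the dataset's five resource tables.

    Returns a tidy frame (patient_id, date, category, cost,
    attribution_level) plus a report. In strict mode an unpriceable event
    aborts the run; in lenient mode it is skipped and counted.
    """
    report = CostingReport()
    frames: list[pd.DataFrame] = []
    cols = ["patient_id", "date", "category", "cost", "attribution_level"]

    def _fail_or_skip(bad: pd.Series, describe) -> pd.Series:
        """Handle unpriceable rows: raise in strict mode, else count them."""
        if bad.any():
            if strict:
                raise UnpriceableEventError(describe(bad))
            report.n_skipped += int(bad.sum())
            report.skipped.append(describe(bad))
        return ~bad

    # prescriptions: exact (product, year) then the BNF average ladder
    rx = dataset.prescriptions
    if len(rx):
        df = rx[["patient_id", "date", "product", "bnf_code"]].copy()
        df["year"] = df["date"].map(lambda d: d.year)
        df["cost"] = [
            schedule.drug_nic.get((p, y)) for p, y in zip(df["product"], df["year"])
        ]
        df["attribution_level"] = np.where(df["cost"].notna(), "exact", "")
        for level in BNF_LADDER_LEVELS:
            miss = df["cost"].isna()
            if not miss.any():
                break
            keys = [
                _bnf_key(str(b), level) for b in df.loc[miss, "bnf_code"]
            ]
            found = [
                schedule.bnf_averages.get((level, k, y)) if k else None
                for k, y in zip(keys, df.loc[miss, "year"])
            ]
            df.loc[miss, "cost"] = found
            df.loc[miss & df["cost"].notna(), "attribution_level"] = level
        keep = _fail_or_skip(
            df["cost"].isna(),
            lambda b: "no NIC at any BNF level for: "
            + ", ".join(sorted(df.loc[b, "bnf_code"].astype(str).unique())),
        )
        df = df[keep]
        factor = df["year"].map(lambda y: schedule.inflation_index.get(y, 1.0))
        df["cost"] = df["cost"].astype(float) * factor
        df["category"] = "prescriptions"
        frames.append(df[cols])

    # consultations: primary care per visit / per hour, outpatient by tariff
    cons = dataset.consultations
    if len(cons):
        prim = cons[cons["consultation_type"] != "outpatient"].copy()
        if len(prim):
            pairs = list(zip(prim["consultation_type"], prim["staff_type"]))
            unit_cost = [schedule.consultation_costs.get(k) for k in pairs]
            keep = _fail_or_skip(
                pd.Series([u is None for u in unit_cost], index=prim.index),
                lambda b: f"no consultation cost for {sorted({pairs[i] for i in np.flatnonzero(b.to_numpy())})}",
            )
            prim = prim[keep]
            unit_cost = [u for u in unit_cost if u is not None]
            values = np.empty(len(prim))
            for i, ((unit, cost), ctype) in enumerate(
                zip(unit_cost, prim["consultation_type"])
            ):
                if unit == "per_visit":
                    values[i] = cost
                else:
                    minutes = schedule.duration_minutes.get(ctype, 0.0)
                    if minutes <= 0:
                        report.n_zero_duration += 1
                    values[i] = cost * minutes / 60.0
            prim = prim.assign(category="primary_care", cost=values,
                               attribution_level="n/a")
            frames.append(prim[cols])
        outp = cons[cons["consultation_type"] == "outpatient"].copy()
        if len(outp):
            tariffs = np.array([
                schedule.outpatient_tariffs.get((d, o), np.nan)
                for d, o in zip(outp["department"], outp["visit_order"])
            ])
            missing = np.isnan(tariffs)
            report.n_default_outpatient += int(missing.sum())
            tariffs[missing] = schedule.default_outpatient_tariff
            outp = outp.assign(category="outpatient", cost=tariffs,
                               attribution_level="n/a")
            frames.append(outp[cols])

    # investigations: same-day grouping into panels
    if len(dataset.tests):
        inv_rows = []
        for (pid, date), day in dataset.tests.groupby(["patient_id", "date"], sort=True):
            try:
                total, _ = group_tests_into_panels(list(day["test_code"]), schedule)
            except UnpriceableEventError as err:
                if strict:
                    raise
                report.n_skipped += len(day)
                report.skipped.append(str(err))
                continue
            inv_rows.append((pid, date, "investigations", total, "n/a"))
        frames.append(pd.DataFrame(inv_rows, columns=cols))

    # admissions: tariff by (group, type), mix-averaged ambiguous day cases
    adm = dataset.admissions
    if len(adm):
        share = schedule.daycase_elective_share
        base = np.empty(len(adm))
        for i, (g, t) in enumerate(zip(adm["group_code"], adm["admission_type"])):
            if t == "daycase_ambiguous":
                el = schedule.admission_tariffs.get((g, "elective"))
                em = schedule.admission_tariffs.get((g, "emergency"))
                base[i] = np.nan if el is None or em is None else share * el + (1 - share) * em
            else:
                base[i] = schedule.admission_tariffs.get((g, t), np.nan)
        bad = pd.Series(np.isnan(base), index=adm.index)
        keep = _fail_or_skip(
            bad, lambda b: "no admission tariff for groups: "
            + ", ".join(sorted(adm.loc[b, "group_code"].unique())),
        )
        adm = adm[keep.to_numpy()].assign(
            category="admissions",
            cost=base[~bad.to_numpy()] * (1.0 + schedule.procedural_uplift),
            attribution_level="n/a",
        )
        frames.append(adm[cols])

    frame = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=cols)
    )
    report.n_costed = len(frame)
    return frame, report


# --------------------------------------------------------------------------
# follow-up windows and summaries
# --------------------------------------------------------------------------

def observation_complete_for_year(
    registration_end: dt.date, index_date: dt.date, k: int
) -> bool:
    """True iff observation covers all of follow-up year k (days
    365(k-1)+1 .. 365k after index; censoring exactly on day 365k counts
    as complete)."""
    if not 1 <= k <= 5:
        raise ValueError(f"follow-up year must be 1..5, got {k}")
    return (registration_end - index_date).days >= YEAR_DAYS * k


def _window(index_date: dt.date, k: int) -> tuple[dt.date, dt.date]:
    lo = index_date + dt.timedelta(days=YEAR_DAYS * (k - 1) + 1)
    hi = index_date + dt.timedelta(days=YEAR_DAYS * k)
    return lo, hi


def _stats(values: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "median": float(np.median(values)),
        "p25": float(np.percentile(values, 25)),
        "p75": float(np.percentile(values, 75)),
    }


def _eligible(cohort: pd.DataFrame, k: int, band: str, group: str) -> pd.DataFrame:
    sel = cohort[cohort["group"] == group]
    if band != "all":
        sel = sel[sel["age_band"] == band]
    ok = [
        observation_complete_for_year(e, i, k)
        for e, i in zip(sel["observation_end"], sel["index_date"])
    ]
    return sel[np.array(ok, dtype=bool)] if len(sel) else sel


def _per_patient_values(
    events: pd.DataFrame,
    eligible: pd.DataFrame,
    k: int,
    value_col: str,
) -> pd.DataFrame:
    """Per eligible patient: category sums (costs) or counts in year-k window.

    Patients with no events contribute zeros in every category.
    """
    pieces = []
    if len(events):
        ev = events.merge(
            eligible[["patient_id", "index_date"]], on="patient_id", how="inner"
        )
        if len(ev):
            offs = np.array([(d - i).days for d, i in zip(ev["date"], ev["index_date"])])
            in_window = (offs >= YEAR_DAYS * (k - 1) + 1) & (offs <= YEAR_DAYS * k)
            ev = ev[in_window]
            if len(ev):
                agg = (
                    ev.groupby(["patient_id", "category"])[value_col]
                    .agg("sum" if value_col == "cost" else "size")
                    .unstack(fill_value=0.0)
                )
                pieces.append(agg)
    base = pd.DataFrame(0.0, index=eligible["patient_id"], columns=list(CATEGORIES))
    if pieces:
        base = base.add(pieces[0].reindex(base.index, fill_value=0.0), fill_value=0.0)
        base = base[[c for c in CATEGORIES]]
    base["total"] = base.sum(axis=1)
    return base


def summarize_annual_costs(
    costed_events: pd.DataFrame,
    cohort: pd.DataFrame,
    k: int,
    band: str = "all",
    group: str = "case",
) -> AnnualCostSummary:
    """Distribution of per-patient annual costs for one group and stratum.

    ``cohort`` is the frame from :func:`cohort_frame` (patient_id, group,
    index_date, age_band, observation_end). Per patient the total is the
    exact sum of the five category costs; the summary reports mean, sd,
    median and quartiles per category and total.
    """
    eligible = _eligible(cohort, k, band, group)
    if eligible.empty:
        return AnnualCostSummary(group, band, k, 0, None)
    per_patient = _per_patient_values(costed_events, eligible, k, "cost")
    stats = {col: _stats(per_patient[col].to_numpy()) for col in per_patient.columns}
    return AnnualCostSummary(group, band, k, len(eligible), stats)


def resource_use_summary(
    events: pd.DataFrame,
    cohort: pd.DataFrame,
    k: int,
    band: str = "all",
    group: str = "case",
) -> AnnualCostSummary:
    """Distribution of per-patient annual event counts per category.

    ``events`` only needs patient_id, date and category (costed or raw).
    """
    eligible = _eligible(cohort, k, band, group)
    if eligible.empty:
        return AnnualCostSummary(group, band, k, 0, None)
    counts = _per_patient_values(events, eligible, k, "category")
    counts = counts.drop(columns="total")
    stats = {col: _stats(counts[col].to_numpy()) for col in counts.columns}
    return AnnualCostSummary(group, band, k, len(eligible), stats)


def event_counts_frame(dataset) -> pd.DataFrame:
    """Raw events as (patient_id, date, category) rows, for resource-use
    counting: prescriptions and tests count per item, consultations split
    into primary care vs outpatient, admissions per admission."""
    parts = []
    rx = dataset.prescriptions[["patient_id", "date"]].copy()
    rx["category"] = "prescriptions"
    parts.append(rx)
    cons = dataset.consultations[["patient_id", "date", "consultation_type"]].copy()
    cons["category"] = np.where(
        cons["consultation_type"] == "outpatient", "outpatient", "primary_care"
    )
    parts.append(cons[["patient_id", "date", "category"]])
    tests = dataset.tests[["patient_id", "date"]].copy()
    tests["category"] = "investigations"
    parts.append(tests)
    adm = dataset.admissions[["patient_id", "date"]].copy()
    adm["category"] = "admissions"
    parts.append(adm)
    return pd.concat(parts, ignore_index=True)


def cohort_frame(cohort_result, patients: pd.DataFrame) -> pd.DataFrame:
    """Cases and controls in one frame for the costing summaries.

    Controls carry the matched case's index date as pseudo-index and their
    own age band at that date; observation runs to each patient's own
    registration end.
    """
    from .cohort import age_group_at  # local import avoids a cycle

    pat = patients.set_index("patient_id")
    rows = []
    for rec in cohort_result.cases.itertuples(index=False):
        rows.append(
            (rec.patient_id, "case", rec.index_date, rec.age_group,
             pat.at[rec.patient_id, "registration_end"])
        )
    for rec in cohort_result.controls.itertuples(index=False):
        by = int(pat.at[rec.patient_id, "birth_year"])
        try:
            band = age_group_at(by, rec.pseudo_index_date)
        except ValueError:  # pseudo-index before the control's imputed birth
            band = "0-5"
        rows.append(
            (rec.patient_id, "control", rec.pseudo_index_date, band,
             pat.at[rec.patient_id, "registration_end"])
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "group", "index_date", "age_band", "observation_end"]
    )
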