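"""Synthetic primary-care EHR generator.

Emulates the relational structure of a UK primary-care research database
with linked hospital admissions: a patient registration spine (practice,
sex, birth year, registration interval, death/transfer censoring) plus five
dated event tables (diagnoses, prescriptions, consultations incl.
outpatient attendances, investigations, admissions), all truncated at the
database's last collection date.

ADHD onset is a discrete-time hazard process on calendar years, with the
hazard per 100,000 configured by age band and sex; age is attained on
1 July (imputed mid-year birthday), so a patient's band for a calendar year
is simply ``year - birth_year``. On onset a first diagnosis is recorded on
the onset day, a confirmatory second diagnosis follows with configurable
probability, and treated patients receive 28-day repeat prescriptions for a
drug drawn from the configured mix, persisting for an exponential time.
Ground truth (onset date, treated flag) is kept alongside so downstream
stages can be validated by parameter recovery.

Every table has its own random stream derived from the master seed, so
regenerating with more patients does not reshuffle unrelated tables, and a
fixed config is reproducible bit for bit.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ADHD_DRUGS, CATEGORIES, CostParams, CountModel, SimulationConfig
from .schedules import CostSchedule, Panel

DAYS_PER_YEAR = 365.25

_STREAMS = (
    "patients",
    "onset",
    "diagnoses",
    "prescriptions",
    "investigations",
    "primary_care",
    "outpatient",
    "admissions",
    "narcolepsy",
    "other_dx",
    "schedules",
)

PATIENT_COLUMNS = [
    "patient_id", "practice_id", "sex", "birth_year",
    "registration_start", "registration_end", "death_date", "transfer_out_date",
]
DIAGNOSIS_COLUMNS = ["row_id", "patient_id", "date", "code"]
PRESCRIPTION_COLUMNS = ["row_id", "patient_id", "date", "product", "bnf_code"]
CONSULTATION_COLUMNS = [
    "row_id", "patient_id", "date", "consultation_type", "staff_type",
    "department", "visit_order",
]
TEST_COLUMNS = ["row_id", "patient_id", "date", "test_code"]
ADMISSION_COLUMNS = ["row_id", "patient_id", "date", "group_code", "admission_type"]
TRUTH_COLUMNS = ["patient_id", "onset_date", "treated", "narcolepsy"]

TEST_CODES = ("FBC", "U_E", "LFT", "TFT", "GLU", "ESR")
PANEL_TESTS = ("FBC", "U_E", "LFT")
DEPARTMENTS = ("paediatrics", "psychiatry", "general_medicine")
CONSULT_TYPES = ("surgery", "clinic", "home_visit", "telephone")
STAFF_TYPES = ("gp", "practice_nurse")
ADMISSION_GROUPS = tuple(f"G{i:02d}" for i in range(1, 9))


@dataclass
class SyntheticDataset:
    """One simulated extract: patient spine, event tables and latent truth."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    consultations: pd.DataFrame
    tests: pd.DataFrame
    admissions: pd.DataFrame
    truth: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _ord(d: dt.date) -> int:
    return d.toordinal()


def _dates(ordinals: np.ndarray) -> pd.Series:
    return pd.Series([dt.date.fromordinal(int(o)) for o in ordinals], dtype="object")


def _year_start_ord(years: np.ndarray) -> np.ndarray:
    uniq = np.unique(years)
    lut = {int(y): dt.date(int(y), 1, 1).toordinal() for y in uniq}
    return np.array([lut[int(y)] for y in years], dtype=np.int64)


def _year_end_ord(years: np.ndarray) -> np.ndarray:
    uniq = np.unique(years)
    lut = {int(y): dt.date(int(y), 12, 31).toordinal() for y in uniq}
    return np.array([lut[int(y)] for y in years], dtype=np.int64)


# --------------------------------------------------------------------------
# patient spine
# --------------------------------------------------------------------------

def _generate_patients(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_patients
    practice = rng.integers(1, cfg.n_practices + 1, n)
    sex = np.where(rng.random(n) < cfg.sex_ratio_male, "M", "F")
    birth_year = rng.integers(cfg.birth_year_min, cfg.birth_year_max + 1, n)
    dob_lut = {
        y: dt.date(y, 7, 1).toordinal()
        for y in range(cfg.birth_year_min, cfg.birth_year_max + 1)
    }
    dob = np.array([dob_lut[int(y)] for y in birth_year], dtype=np.int64)

    reg = cfg.registration
    start = rng.integers(_ord(reg.start_min), _ord(reg.start_max) + 1, n)
    start = np.maximum(start, dob)

    def _exp_days(p_per_year: float) -> np.ndarray:
        if p_per_year <= 0:
            return np.full(n, np.iinfo(np.int64).max // 4, dtype=np.int64)
        return np.rint(rng.exponential(1.0 / p_per_year, n) * DAYS_PER_YEAR).astype(np.int64)

    death_ord = start + _exp_days(reg.p_death_per_year)
    transfer_ord = start + _exp_days(reg.p_transfer_per_year)
    last = _ord(cfg.db_last_collection)

    # censoring hierarchy: death, then transfer-out, then collection truncation
    end = np.minimum(np.minimum(death_ord, transfer_ord), last)
    died = (death_ord <= transfer_ord) & (death_ord <= last)
    moved = ~died & (transfer_ord <= last)

    death_date = pd.Series([None] * n, dtype="object")
    death_date[died] = _dates(death_ord[died]).values
    transfer_date = pd.Series([None] * n, dtype="object")
    transfer_date[moved] = _dates(transfer_ord[moved]).values

    return pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1, dtype=np.int64),
            "practice_id": practice.astype(np.int64),
            "sex": sex,
            "birth_year": birth_year.astype(np.int64),
            "registration_start": _dates(start),
            "registration_end": _dates(end),
            "death_date": death_date,
            "transfer_out_date": transfer_date,
        }
    )


# --------------------------------------------------------------------------
# patient-year expansion
# --------------------------------------------------------------------------

def _patient_years(patients: pd.DataFrame) -> pd.DataFrame:
    """One row per (patient, registered calendar year), with the overlap of
    the registration interval and the year in day ordinals."""
    if patients.empty:
        return pd.DataFrame(
            columns=["patient_id", "sex", "birth_year", "year", "start_ord", "end_ord", "days"]
        )
    start = patients["registration_start"].map(dt.date.toordinal).to_numpy(np.int64)
    end = patients["registration_end"].map(dt.date.toordinal).to_numpy(np.int64)
    y0 = patients["registration_start"].map(lambda d: d.year).to_numpy(np.int64)
    y1 = patients["registration_end"].map(lambda d: d.year).to_numpy(np.int64)
    counts = y1 - y0 + 1
    idx = np.repeat(np.arange(len(patients)), counts)
    offsets = np.concatenate([np.arange(c) for c in counts])
    year = y0[idx] + offsets
    row_start = np.maximum(start[idx], _year_start_ord(year))
    row_end = np.minimum(end[idx], _year_end_ord(year))
    return pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy()[idx],
            "sex": patients["sex"].to_numpy()[idx],
            "birth_year": patients["birth_year"].to_numpy()[idx],
            "year": year,
            "start_ord": row_start,
            "end_ord": row_end,
            "days": row_end - row_start + 1,
        }
    )


# --------------------------------------------------------------------------
# onset process
# --------------------------------------------------------------------------

def _band_index(age: np.ndarray) -> np.ndarray:
    """0 for ages 0-5, 1 for 6-17, 2 for >=18."""
    return np.clip(np.digitize(age, [6, 18]), 0, 2)


def _draw_onsets(
    cfg: SimulationConfig, py: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """First-hit discrete-time hazard on patient-years -> onset ordinal."""
    if py.empty:
        return pd.DataFrame(columns=["patient_id", "onset_ord"])
    age = py["year"].to_numpy() - py["birth_year"].to_numpy()
    band = _band_index(age)
    hazard = np.zeros(len(py))
    for bi, bname in enumerate(("0-5", "6-17", "18+")):
        for sex in ("M", "F"):
            mask = (band == bi) & (py["sex"].to_numpy() == sex)
            hazard[mask] = cfg.incidence_truth[bname][sex]
    p = hazard / 1e5 * py["days"].to_numpy() / DAYS_PER_YEAR
    u = rng.random(len(py))
    u_day = rng.random(len(py))  # drawn for every row to keep streams aligned
    hit = u < p
    if not hit.any():
        return pd.DataFrame(columns=["patient_id", "onset_ord"])
    onset_ord = (
        py["start_ord"].to_numpy() + np.floor(u_day * py["days"].to_numpy()).astype(np.int64)
    )
    hits = pd.DataFrame(
        {"patient_id": py["patient_id"].to_numpy()[hit], "onset_ord": onset_ord[hit]}
    )
    # first onset per patient only; rows are already in year order
    return hits.groupby("patient_id", as_index=False).first()


# --------------------------------------------------------------------------
# clinical records for cases
# --------------------------------------------------------------------------

def _case_records(
    cfg: SimulationConfig,
    onsets: pd.DataFrame,
    reg_end: dict[int, int],
    rng_dx: np.random.Generator,
    rng_rx: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Diagnosis rows, ADHD prescription rows and the truth table for cases."""
    dx_rows: list[tuple[int, int, str]] = []  # (patient, ordinal, code)
    rx_rows: list[tuple[int, int, str, str]] = []  # (patient, ordinal, product, bnf)
    truth_rows: list[tuple[int, int, bool]] = []

    drugs = sorted(cfg.drug_mix)
    probs = np.array([cfg.drug_mix[d] for d in drugs])

    for rec in onsets.itertuples(index=False):
        pid, onset = int(rec.patient_id), int(rec.onset_ord)
        end = reg_end[pid]
        dx_rows.append((pid, onset, "ADHD"))
        if rng_dx.random() < cfg.p_record_second_diagnosis:
            # confirmatory diagnosis, truncated at the censor date
            dx2 = min(onset + int(rng_dx.integers(30, 183)), end)
            dx_rows.append((pid, dx2, "ADHD"))
        treated = rng_rx.random() < cfg.p_treated
        truth_rows.append((pid, onset, treated))
        if treated:
            drug = drugs[int(rng_rx.choice(len(drugs), p=probs))]
            first_rx = min(onset + int(rng_rx.integers(0, 61)), end)
            persist_days = max(
                60, int(rng_rx.exponential(cfg.mean_treatment_years) * DAYS_PER_YEAR)
            )
            stop = min(first_rx + persist_days, end)
            for day in range(first_rx, stop + 1, 28):
                rx_rows.append((pid, day, drug, "4.4.0"))

    dx = pd.DataFrame(dx_rows, columns=["patient_id", "ord", "code"])
    rx = pd.DataFrame(rx_rows, columns=["patient_id", "ord", "product", "bnf_code"])
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "onset_ord", "treated"])
    return dx, rx, truth


def _background_diagnoses(
    cfg: SimulationConfig, py: pd.DataFrame, rng: np.random.Generator, rate: float = 0.15
) -> pd.DataFrame:
    """Sparse non-ADHD coded diagnoses, to exercise code-set filtering."""
    if py.empty:
        return pd.DataFrame(columns=["patient_id", "ord", "code"])
    lam = rate * py["days"].to_numpy() / DAYS_PER_YEAR
    counts = rng.poisson(lam)
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=["patient_id", "ord", "code"])
    idx = np.repeat(np.arange(len(py)), counts)
    day = py["start_ord"].to_numpy()[idx] + np.floor(
        rng.random(total) * py["days"].to_numpy()[idx]
    ).astype(np.int64)
    code = np.char.add("OTH", rng.integers(1, 21, total).astype(str))
    return pd.DataFrame(
        {"patient_id": py["patient_id"].to_numpy()[idx], "ord": day, "code": code}
    )


def _narcolepsy(
    cfg: SimulationConfig, patients: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    if patients.empty or cfg.narcolepsy_rate <= 0:
        return pd.DataFrame(columns=["patient_id", "ord", "code"])
    start = patients["registration_start"].map(dt.date.toordinal).to_numpy(np.int64)
    end = patients["registration_end"].map(dt.date.toordinal).to_numpy(np.int64)
    days = end - start + 1
    p = cfg.narcolepsy_rate / 1e5 * days / DAYS_PER_YEAR
    u = rng.random(len(patients))
    u_day = rng.random(len(patients))
    hit = u < p
    day = start + np.floor(u_day * days).astype(np.int64)
    return pd.DataFrame(
        {
            "patient_id": patients["patient_id"].to_numpy()[hit],
            "ord": day[hit],
            "code": "NARC",
        }
    )


# --------------------------------------------------------------------------
# resource-use event streams
# --------------------------------------------------------------------------

def _zinb_counts(
    rng: np.random.Generator, model: CountModel, frac: np.ndarray
) -> np.ndarray:
    """Zero-inflated gamma-Poisson annual counts, scaled by exposure fraction."""
    n = len(frac)
    active = rng.random(n) >= model.p_zero
    mean = np.maximum(model.mean * frac, 1e-12)
    lam = rng.gamma(model.dispersion, mean / model.dispersion)
    counts = rng.poisson(lam)
    counts[~active] = 0
    return counts


def _category_events(
    cfg: SimulationConfig,
    py: pd.DataFrame,
    onset_year: dict[int, int],
    category: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Dated events for one resource category; returns patient_id and ordinal."""
    if py.empty:
        return pd.DataFrame({"patient_id": pd.Series(dtype=np.int64),
                             "ord": pd.Series(dtype=np.int64)})
    pids = py["patient_id"].to_numpy()
    years = py["year"].to_numpy()
    oy = np.array([onset_year.get(int(p), 1 << 30) for p in pids])
    is_case_year = years >= oy
    frac = py["days"].to_numpy() / DAYS_PER_YEAR
    counts = np.zeros(len(py), dtype=np.int64)
    for flag, model in ((False, cfg.resource_intensity.control[category]),
                        (True, cfg.resource_intensity.case[category])):
        mask = is_case_year == flag
        if mask.any():
            counts[mask] = _zinb_counts(rng, model, frac[mask])
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame({"patient_id": pd.Series(dtype=np.int64),
                             "ord": pd.Series(dtype=np.int64)})
    idx = np.repeat(np.arange(len(py)), counts)
    day = py["start_ord"].to_numpy()[idx] + np.floor(
        rng.random(total) * py["days"].to_numpy()[idx]
    ).astype(np.int64)
    return pd.DataFrame({"patient_id": pids[idx], "ord": day})


def _choice(rng: np.random.Generator, options: tuple[str, ...], probs: list[float],
            n: int) -> np.ndarray:
    return np.array(options, dtype=object)[rng.choice(len(options), size=n, p=probs)]


# --------------------------------------------------------------------------
# product catalogue (shared by dataset and schedule generation)
# --------------------------------------------------------------------------

def _product_catalogue(cp: CostParams, rng: np.random.Generator) -> pd.DataFrame:
    """Drug catalogue: product, BNF code, base NIC and whether the product
    gets an exact (product, year) price in the schedule.

    ADHD drugs sit in BNF chapter 4 (CNS), section 4.4, sub-paragraph 4.4.0
    and are always exact-priced; other products spread across chapters.
    """
    rows = [
        ("methylphenidate", "4.4.0", 28.0, True),
        ("atomoxetine", "4.4.0", 55.0, True),
        ("dexamfetamine", "4.4.0", 12.0, True),
    ]
    for i in range(cp.n_other_products):
        chapter = str(1 + i % 9)
        section = f"{chapter}.{1 + (i // 9) % 3}"
        subpara = f"{section}.{1 + (i // 27) % 3}"
        nic = float(np.exp(rng.normal(cp.nic_log_mean, cp.nic_log_sd)))
        exact = bool(rng.random() < cp.p_exact_priced)
        rows.append((f"P{i + 1:03d}", subpara, round(nic, 2), exact))
    return pd.DataFrame(rows, columns=["product", "bnf_code", "base_nic", "exact_priced"])


# --------------------------------------------------------------------------
# public API
# --------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Simulate a full synthetic extract under ``config``.

    Deterministic for a fixed seed. With ``n_patients == 0`` all tables are
    empty but well-formed.
    """
    rngs = _rngs(config.seed)
    patients = _generate_patients(config, rngs["patients"])
    py = _patient_years(patients)
    reg_end = {
        int(p): dt.date.toordinal(e)
        for p, e in zip(patients["patient_id"], patients["registration_end"])
    }

    onsets = _draw_onsets(config, py, rngs["onset"])
    case_dx, adhd_rx, truth_cases = _case_records(
        config, onsets, reg_end, rngs["diagnoses"], rngs["prescriptions"]
    )
    other_dx = _background_diagnoses(config, py, rngs["other_dx"])
    narc = _narcolepsy(config, patients, rngs["narcolepsy"])
    dx_all = pd.concat([case_dx, other_dx, narc], ignore_index=True)

    onset_year = {
        int(r.patient_id): dt.date.fromordinal(int(r.onset_ord)).year
        for r in truth_cases.itertuples(index=False)
    }

    # non-ADHD prescriptions
    rx_bg = _category_events(config, py, onset_year, "prescriptions", rngs["prescriptions"])
    catalogue = _product_catalogue(config.cost_params, np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[_STREAMS.index("schedules")]
    ))
    others = catalogue[~catalogue["product"].isin(ADHD_DRUGS)].reset_index(drop=True)
    if len(rx_bg) and len(others):
        pick = rngs["prescriptions"].integers(0, len(others), len(rx_bg))
        rx_bg = rx_bg.assign(
            product=others["product"].to_numpy()[pick],
            bnf_code=others["bnf_code"].to_numpy()[pick],
        )
    else:
        rx_bg = rx_bg.assign(product=pd.Series(dtype=object), bnf_code=pd.Series(dtype=object))
    rx_all = pd.concat([adhd_rx, rx_bg], ignore_index=True)

    # primary-care consultations + outpatient attendances share one table
    cons = _category_events(config, py, onset_year, "primary_care", rngs["primary_care"])
    n_c = len(cons)
    cons = cons.assign(
        consultation_type=_choice(rngs["primary_care"], CONSULT_TYPES,
                                  [0.60, 0.10, 0.05, 0.25], n_c),
        staff_type=_choice(rngs["primary_care"], STAFF_TYPES, [0.7, 0.3], n_c),
        department="",
        visit_order="",
    )
    outp = _category_events(config, py, onset_year, "outpatient", rngs["outpatient"])
    n_o = len(outp)
    outp = outp.assign(
        consultation_type="outpatient",
        staff_type="",
        department=_choice(rngs["outpatient"], DEPARTMENTS, [0.45, 0.35, 0.20], n_o),
        visit_order=_choice(rngs["outpatient"], ("first", "follow_up"), [0.3, 0.7], n_o),
    )
    consultations = pd.concat([cons, outp], ignore_index=True)

    # investigations: ~30% of draws are same-day three-test panel days
    tests = _category_events(config, py, onset_year, "investigations", rngs["investigations"])
    n_t = len(tests)
    is_panel = rngs["investigations"].random(n_t) < 0.3
    single_code = _choice(
        rngs["investigations"], TEST_CODES, [0.25, 0.20, 0.15, 0.15, 0.15, 0.10], n_t
    )
    singles = tests[~is_panel].assign(test_code=single_code[~is_panel])
    panel_days = tests[is_panel]
    panels = pd.concat(
        [panel_days.assign(test_code=c) for c in PANEL_TESTS], ignore_index=True
    ) if len(panel_days) else pd.DataFrame(columns=[*tests.columns, "test_code"])
    tests_all = pd.concat([singles, panels], ignore_index=True)

    adm = _category_events(config, py, onset_year, "admissions", rngs["admissions"])
    n_a = len(adm)
    adm = adm.assign(
        group_code=np.array(ADMISSION_GROUPS, dtype=object)[
            rngs["admissions"].integers(0, len(ADMISSION_GROUPS), n_a)
        ],
        admission_type=_choice(
            rngs["admissions"], ("elective", "emergency", "daycase_ambiguous"),
            [0.35, 0.50, 0.15], n_a
        ),
    )

    def _finish(df: pd.DataFrame, cols: list[str], extra_sort: list[str]) -> pd.DataFrame:
        out = df.copy()
        if out.empty:
            return pd.DataFrame(columns=cols)
        out["date"] = _dates(out.pop("ord").to_numpy())
        out = out.sort_values(
            ["patient_id", "date", *extra_sort], kind="stable"
        ).reset_index(drop=True)
        out.insert(0, "row_id", np.arange(1, len(out) + 1, dtype=np.int64))
        return out[cols]

    diagnoses = _finish(dx_all, DIAGNOSIS_COLUMNS, ["code"])
    prescriptions = _finish(rx_all, PRESCRIPTION_COLUMNS, ["product"])
    consultations = _finish(consultations, CONSULTATION_COLUMNS,
                            ["consultation_type", "department"])
    tests_all = _finish(tests_all, TEST_COLUMNS, ["test_code"])
    admissions = _finish(adm, ADMISSION_COLUMNS, ["group_code"])

    narc_ids = set(narc["patient_id"].tolist())
    truth = patients[["patient_id"]].copy()
    truth = truth.merge(truth_cases, on="patient_id", how="left")
    truth["onset_date"] = truth["onset_ord"].map(
        lambda o: dt.date.fromordinal(int(o)) if pd.notna(o) else None
    )
    truth["treated"] = truth["treated"].map(lambda v: bool(v) if pd.notna(v) else False)
    truth["narcolepsy"] = truth["patient_id"].isin(narc_ids)
    truth = truth[TRUTH_COLUMNS]

    return SyntheticDataset(
        patients=patients,
        diagnoses=diagnoses,
        prescriptions=prescriptions,
        consultations=consultations,
        tests=tests_all,
        admissions=admissions,
        truth=truth,
    )


def generate_reference_schedules(config: SimulationConfig) -> CostSchedule:
    """Build the synthetic tariff schedules matching the generator's catalogue.

    Nominal drug prices drift with the configured inflation rate; the
    inflation index converts each year back to 2011 pounds (factor 1 in
    2011). BNF-level average NICs are computed from the exact-priced
    products, so every product's chapter is covered by construction.
    """
    cp = config.cost_params
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(len(_STREAMS))[_STREAMS.index("schedules")]
    )
    catalogue = _product_catalogue(cp, rng)
    years = range(cp.schedule_year_min, cp.schedule_year_max + 1)

    drug_nic: dict[tuple[str, int], float] = {}
    level_values: dict[tuple[str, str, int], list[float]] = {}
    for rec in catalogue.itertuples(index=False):
        subpara = rec.bnf_code
        section = ".".join(subpara.split(".")[:2])
        chapter = subpara.split(".")[0]
        for y in years:
            nic = round(rec.base_nic * (1.0 + cp.annual_inflation) ** (y - 2011), 4)
            if rec.exact_priced:
                drug_nic[(rec.product, y)] = nic
            # averages are over all catalogue products so no chapter is empty
            for level, key in (("sub_paragraph", subpara), ("section", section),
                               ("chapter", chapter)):
                level_values.setdefault((level, key, y), []).append(nic)
    bnf_averages = {k: round(float(np.mean(v)), 4) for k, v in level_values.items()}

    inflation = {y: round((1.0 + cp.annual_inflation) ** (2011 - y), 6) for y in years}
    inflation[2011] = 1.0

    consultation_costs = {
        ("surgery", "gp"): ("per_visit", 36.0),
        ("surgery", "practice_nurse"): ("per_visit", 13.0),
        ("clinic", "gp"): ("per_hour", 140.0),
        ("clinic", "practice_nurse"): ("per_hour", 42.0),
        ("home_visit", "gp"): ("per_visit", 114.0),
        ("home_visit", "practice_nurse"): ("per_hour", 42.0),
        ("telephone", "gp"): ("per_visit", 22.0),
        ("telephone", "practice_nurse"): ("per_visit", 8.0),
    }
    durations = {"surgery": 11.7, "clinic": 17.2, "home_visit": 23.4, "telephone": 7.1}

    investigation_tariffs = {
        "FBC": 3.0, "U_E": 2.5, "LFT": 2.0, "TFT": 4.0, "GLU": 1.5, "ESR": 2.8,
    }
    panels = [
        Panel("PAN_HAEM_BIO", frozenset(PANEL_TESTS), 5.5),
        Panel("PAN_RENAL", frozenset({"U_E", "GLU"}), 3.2),
    ]
    outpatient_tariffs = {
        ("paediatrics", "first"): 250.0,
        ("paediatrics", "follow_up"): 150.0,
        ("psychiatry", "first"): 230.0,
        ("psychiatry", "follow_up"): 140.0,
        ("general_medicine", "first"): 190.0,
        ("general_medicine", "follow_up"): 110.0,
    }
    admission_tariffs: dict[tuple[str, str], float] = {}
    for g in ADMISSION_GROUPS:
        elective = round(float(np.exp(rng.normal(7.0, 0.4))), 2)
        admission_tariffs[(g, "elective")] = elective
        admission_tariffs[(g, "emergency")] = round(
            elective * float(rng.uniform(1.1, 1.5)), 2
        )

    return CostSchedule(
        drug_nic=drug_nic,
        bnf_averages=bnf_averages,
        inflation_index=inflation,
        consultation_costs=consultation_costs,
        duration_minutes=durations,
        investigation_tariffs=investigation_tariffs,
        panels=panels,
        outpatient_tariffs=outpatient_tariffs,
        admission_tariffs=admission_tariffs,
        daycase_elective_share=cp.daycase_elective_share,
        procedural_uplift=cp.procedural_uplift,
        default_outpatient_tariff=cp.default_outpatient_tariff,
    )


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def write_dataset(ds: SyntheticDataset, directory: str | Path) -> pd.DataFrame:
    """Write every table as CSV plus a manifest of row counts and checksums.

    On any I/O failure the files already written are removed before the
    error propagates, so a directory never holds a partial extract.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest_rows = []
    try:
        for name, df in ds.tables().items():
            path = directory / f"{name}.csv"
            df.to_csv(path, index=False)
            written.append(path)
            digest = hashlib.sha256(path.read_bytes()).hexdigest()
            manifest_rows.append((name, len(df), digest))
        manifest = pd.DataFrame(manifest_rows, columns=["table", "n_rows", "sha256"])
        manifest.to_csv(directory / "manifest.csv", index=False)
        written.append(directory / "manifest.csv")
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return manifest


_DATE_COLS = {
    "patients": ["registration_start", "registration_end", "death_date", "transfer_out_date"],
    "diagnoses": ["date"],
    "prescriptions": ["date"],
    "consultations": ["date"],
    "tests": ["date"],
    "admissions": ["date"],
    "truth": ["onset_date"],
}


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Load a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    frames = {}
    for name in _DATE_COLS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing table file: {path}")
        df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        for col in _DATE_COLS[name]:
            if col in df.columns:
                df[col] = df[col].map(
                    lambda s: dt.date.fromisoformat(s) if isinstance(s, str) and s else None
                )
        for col in ("department", "visit_order", "staff_type"):
            if col in df.columns:
                df[col] = df[col].fillna("") if df[col].dtype == object else df[col]
        if name == "truth" and "treated" in df.columns:
            df["treated"] = df["treated"].astype(bool)
            df["narcolepsy"] = df["narcolepsy"].astype(bool)
        frames[name] = df
    return SyntheticDataset(**frames)
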