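"""Shared builders and fixtures: hand-rolled micro-frames for rule tests and
a small simulated dataset reused across modules."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from ehrepi import (
    CohortDefinition,
    CostSchedule,
    Panel,
    SimulationConfig,
    generate_dataset,
    generate_reference_schedules,
)


def d(s: str) -> dt.date:
    return dt.date.fromisoformat(s)


def patients_frame(rows: list[dict]) -> pd.DataFrame:
    defaults = dict(
        practice_id=1, sex="M", birth_year=1992,
        registration_start=d("1995-01-01"), registration_end=d("2010-12-31"),
        death_date=None, transfer_out_date=None,
    )
    out = []
    for row in rows:
        rec = {**defaults, **row}
        for col in ("registration_start", "registration_end", "death_date",
                    "transfer_out_date"):
            if isinstance(rec[col], str):
                rec[col] = d(rec[col])
        out.append(rec)
    cols = ["patient_id", "practice_id", "sex", "birth_year",
            "registration_start", "registration_end", "death_date",
            "transfer_out_date"]
    return pd.DataFrame(out)[cols]


def diagnoses_frame(rows: list[tuple]) -> pd.DataFrame:
    """rows: (patient_id, date, code)"""
    recs = [
        {"row_id": i + 1, "patient_id": p, "date": d(dd) if isinstance(dd, str) else dd,
         "code": c}
        for i, (p, dd, c) in enumerate(rows)
    ]
    return pd.DataFrame(recs, columns=["row_id", "patient_id", "date", "code"])


def prescriptions_frame(rows: list[tuple]) -> pd.DataFrame:
    """rows: (patient_id, date, product[, bnf_code])"""
    recs = []
    for i, row in enumerate(rows):
        p, dd, prod = row[:3]
        bnf = row[3] if len(row) > 3 else "4.4.0"
        recs.append(
            {"row_id": i + 1, "patient_id": p,
             "date": d(dd) if isinstance(dd, str) else dd,
             "product": prod, "bnf_code": bnf}
        )
    return pd.DataFrame(
        recs, columns=["row_id", "patient_id", "date", "product", "bnf_code"]
    )


@pytest.fixture(scope="session")
def defn() -> CohortDefinition:
    return CohortDefinition()


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    # onset hazards are raised well above the defaults so a small fixture
    # still contains enough cases to exercise every downstream path
    return SimulationConfig(
        n_patients=800,
        n_practices=6,
        seed=20250920,
        incidence_truth={
            "0-5": {"M": 300.0, "F": 200.0},
            "6-17": {"M": 900.0, "F": 300.0},
            "18+": {"M": 200.0, "F": 150.0},
        },
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_schedule(small_config):
    return generate_reference_schedules(small_config)


@pytest.fixture()
def toy_schedule() -> CostSchedule:
    """Hand-written schedule with the arithmetic worked through by hand."""
    return CostSchedule(
        drug_nic={
            ("drugX", 2005): 12.50,
            ("methylphenidate", 2005): 30.0,
        },
        bnf_averages={
            ("sub_paragraph", "2.1.1", 2005): 8.00,
            ("section", "2.1", 2005): 9.50,
            ("chapter", "2", 2005): 11.00,
        },
        inflation_index={2005: 1.20, 2011: 1.0},
        consultation_costs={
            ("surgery", "gp"): ("per_visit", 36.0),
            ("clinic", "gp"): ("per_hour", 140.0),
            ("drop_in", "nurse"): ("per_hour", 60.0),
        },
        duration_minutes={"surgery": 11.7, "clinic": 11.7, "drop_in": 0.0},
        investigation_tariffs={"A": 4.0, "B": 3.0, "C": 6.0, "D": 1.0, "E": 2.5},
        panels=[
            Panel("PAN_AB", frozenset({"A", "B"}), 5.0),
            Panel("PAN_ABC", frozenset({"A", "B", "C"}), 9.0),
            Panel("PAN_DE", frozenset({"D", "E"}), 2.0),
        ],
        outpatient_tariffs={
            ("paediatrics", "first"): 250.0,
            ("paediatrics", "follow_up"): 150.0,
        },
        admission_tariffs={
            ("G01", "elective"): 1000.0,
            ("G01", "emergency"): 1200.0,
            ("G02", "elective"): 800.0,
            ("G02", "emergency"): 1200.0,
        },
        daycase_elective_share=0.6,
        procedural_uplift=0.175,
        default_outpatient_tariff=120.0,
    )
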