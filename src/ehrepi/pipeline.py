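"""End-to-end orchestration: simulate -> cohort -> rates -> costs -> tables.

Also provides the case/control cost comparison (Welch unequal-variance
test plus a bootstrap p-value as a skew-robust companion — healthcare cost
distributions are strongly right-skewed) and study-style table rendering.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from .cohort import CohortResult, build_cohort
from .config import AGE_BANDS, CATEGORIES, RunConfig
from .costing import (
    AnnualCostSummary,
    CostingReport,
    cohort_frame,
    cost_events,
    event_counts_frame,
    resource_use_summary,
    summarize_annual_costs,
)
from .epidemiology import (
    annotate_cases,
    build_person_time_ledger,
    incidence_series,
    prevalence_series,
)
from .schedules import CostSchedule
from .simulate import (
    SyntheticDataset,
    generate_dataset,
    generate_reference_schedules,
    read_dataset,
    write_dataset,
)


@dataclass
class CostComparison:
    n_case: int
    n_control: int
    mean_case: float
    mean_control: float
    t_statistic: float
    p_welch: float
    p_bootstrap: Optional[float]


def compare_costs(
    case_totals: np.ndarray,
    control_totals: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> CostComparison:
    """Two-sided unequal-variance comparison of annual total costs.

    The Welch t statistic is reported alongside a two-sided bootstrap
    p-value for the difference in means (resampling each group with
    replacement under the null of shifted means), which is robust to the
    heavy right skew of cost data. Requires at least two observations per
    group.
    """
    case_totals = np.asarray(case_totals, dtype=float)
    control_totals = np.asarray(control_totals, dtype=float)
    if len(case_totals) < 2 or len(control_totals) < 2:
        raise ValueError("need at least two observations in each group")
    t_stat, p_welch = sps.ttest_ind(case_totals, control_totals, equal_var=False)

    p_boot: Optional[float] = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        observed = case_totals.mean() - control_totals.mean()
        # centre both groups on the pooled mean to impose the null
        pooled = np.concatenate([case_totals, control_totals]).mean()
        a = case_totals - case_totals.mean() + pooled
        b = control_totals - control_totals.mean() + pooled
        diffs = np.empty(n_boot)
        for i in range(n_boot):
            diffs[i] = (
                rng.choice(a, size=len(a), replace=True).mean()
                - rng.choice(b, size=len(b), replace=True).mean()
            )
        p_boot = float((np.sum(np.abs(diffs) >= abs(observed)) + 1) / (n_boot + 1))
    return CostComparison(
        n_case=len(case_totals),
        n_control=len(control_totals),
        mean_case=float(case_totals.mean()),
        mean_control=float(control_totals.mean()),
        t_statistic=float(t_stat),
        p_welch=float(p_welch),
        p_bootstrap=p_boot,
    )


# --------------------------------------------------------------------------
# table rendering
# --------------------------------------------------------------------------

def summaries_frame(summaries: list[AnnualCostSummary]) -> pd.DataFrame:
    """Tidy frame of annual summaries: one row per (stratum, year, group,
    category); not-computed cells (empty groups) carry missing values, not
    zeros."""
    rows = []
    for s in summaries:
        cats = list(CATEGORIES) + ["total"] if s.stats and "total" in s.stats else list(CATEGORIES)
        if s.stats is None:
            for cat in list(CATEGORIES) + ["total"]:
                rows.append(
                    {"age_band": s.age_band, "followup_year": s.followup_year,
                     "group": s.group, "category": cat, "n": 0, "computed": False,
                     **{k: pd.NA for k in ("mean", "sd", "median", "p25", "p75")}}
                )
            continue
        for cat in cats:
            rows.append(
                {"age_band": s.age_band, "followup_year": s.followup_year,
                 "group": s.group, "category": cat, "n": s.n, "computed": True,
                 **{k: round(v, 2) for k, v in s.stats[cat].items()}}
            )
    return pd.DataFrame(rows)


def baseline_table(cohort: CohortResult, patients: pd.DataFrame) -> pd.DataFrame:
    """Baseline characteristics (N, sex split, mean age) by group and band."""
    cases = annotate_cases(cohort.cases, patients)
    controls = cohort.controls.merge(
        patients[["patient_id", "sex", "birth_year"]], on="patient_id", how="left"
    )
    controls["age_at_index"] = [
        max((d.year - by) - (1 if (d.month, d.day) < (7, 1) else 0), 0)
        for by, d in zip(controls["birth_year"], controls["pseudo_index_date"])
    ]
    rows = []
    for band in ("all", *AGE_BANDS):
        for group, df in (("case", cases), ("control", controls)):
            if band != "all":
                sel = df[[a >= 18 if band == "18+" else
                          (6 <= a <= 17 if band == "6-17" else a <= 5)
                          for a in df["age_at_index"]]]
            else:
                sel = df
            n = len(sel)
            males = int((sel["sex"] == "M").sum())
            rows.append(
                {"age_band": band, "group": group, "n": n,
                 "males": males,
                 "male_pct": round(100.0 * males / n) if n else pd.NA,
                 "age_mean": round(float(sel["age_at_index"].mean()), 1) if n else pd.NA,
                 "age_sd": round(float(sel["age_at_index"].std(ddof=1)), 1) if n > 1 else pd.NA}
            )
    return pd.DataFrame(rows)


def render_text_table(df: pd.DataFrame, currency_cols: tuple[str, ...] = ()) -> str:
    """Aligned text rendering; currency columns get pounds with thousands
    separators; missing cells render as 'NC' (not computed), never 0."""
    show = df.copy()
    for col in currency_cols:
        if col in show.columns:
            show[col] = [
                "NC" if pd.isna(v) else f"£{v:,.0f}" for v in show[col]
            ]
    for col in show.columns:
        show[col] = ["NC" if (not isinstance(v, str) and pd.isna(v)) else v
                     for v in show[col]]
    return show.to_string(index=False)


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all outputs under ``config.out_dir``.

    Returns the provenance report (also written as ``provenance.json``):
    seed, package version, per-stage timings, row counts, exclusion
    tallies and output checksums. Idempotent for fixed inputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": json.loads(config.model_dump_json()),
        "stages": {},
    }

    def _stage(name):
        t0 = time.perf_counter()

        def _done(**info):
            report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3), **info}

        return _done

    # ---- data ------------------------------------------------------------
    done = _stage("simulate")
    if config.dataset_dir is not None:
        ds = read_dataset(config.dataset_dir)
    else:
        sim_cfg = config.simulation.model_copy(update={"seed": config.seed})
        ds = generate_dataset(sim_cfg)
        write_dataset(ds, out / "dataset")
    if config.schedule_dir is not None:
        schedule = CostSchedule.from_dir(config.schedule_dir)
    else:
        sim_cfg = config.simulation.model_copy(update={"seed": config.seed})
        schedule = generate_reference_schedules(sim_cfg)
        schedule.to_dir(out / "schedules")
    done(rows={name: len(df) for name, df in ds.tables().items()})

    # ---- cohort ----------------------------------------------------------
    done = _stage("cohort")
    cohort = build_cohort(ds.patients, ds.diagnoses, ds.prescriptions,
                          config.cohort, config.seed)
    cases_x = annotate_cases(cohort.cases, ds.patients)
    cases_x.to_csv(out / "cases.csv", index=False)
    cohort.controls.to_csv(out / "controls.csv", index=False)
    cohort.exclusions.to_csv(out / "exclusions.csv", index=False)
    done(
        n_cases=len(cohort.cases),
        n_controls=len(cohort.controls),
        exclusions=cohort.exclusions["reason"].value_counts().to_dict()
        if len(cohort.exclusions) else {},
        n_shortfall_cases=len(cohort.shortfall),
    )

    # ---- rates -----------------------------------------------------------
    done = _stage("rates")
    years = config.analysis_years or list(
        range(config.simulation.study_start.year, config.simulation.study_end.year + 1)
    )
    ledger = build_person_time_ledger(
        ds.patients, cohort.cases, years[0], years[-1]
    )
    rates = incidence_series(cases_x, ledger, years)
    rates.to_csv(out / "rates.csv", index=False)
    prev = prevalence_series(
        ds.patients, cohort.cases, ds.diagnoses, ds.prescriptions,
        config.cohort, years, config.simulation.db_last_collection,
    )
    prev.to_csv(out / "prevalence.csv", index=False)
    done(n_rate_rows=len(rates), n_prevalence_rows=len(prev))

    # ---- costs -----------------------------------------------------------
    done = _stage("costs")
    costed, costing_report = cost_events(ds, schedule, strict=config.strict_costing)
    cframe = cohort_frame(cohort, ds.patients)
    raw_counts = event_counts_frame(ds)
    cost_summaries: list[AnnualCostSummary] = []
    use_summaries: list[AnnualCostSummary] = []
    for band in ("all", *AGE_BANDS):
        for k in range(1, config.followup_years + 1):
            for group in ("case", "control"):
                cost_summaries.append(
                    summarize_annual_costs(costed, cframe, k, band, group)
                )
                use_summaries.append(
                    resource_use_summary(raw_counts, cframe, k, band, group)
                )
    costs_df = summaries_frame(cost_summaries)
    use_df = summaries_frame(use_summaries)
    costs_df.to_csv(out / "costs_by_year.csv", index=False)
    use_df.to_csv(out / "resource_use.csv", index=False)
    baseline = baseline_table(cohort, ds.patients)
    baseline.to_csv(out / "baseline.csv", index=False)
    (out / "costs_by_year.txt").write_text(
        render_text_table(costs_df, ("mean", "sd", "median", "p25", "p75")) + "\n"
    )
    done(
        n_costed=costing_report.n_costed,
        n_skipped=costing_report.n_skipped,
        n_default_outpatient=costing_report.n_default_outpatient,
    )

    # ---- comparison ------------------------------------------------------
    done = _stage("comparison")
    comparison = None
    year1 = _year1_totals(costed, cframe)
    if len(year1["case"]) >= 2 and len(year1["control"]) >= 2:
        comparison = compare_costs(
            year1["case"], year1["control"],
            n_boot=config.bootstrap_reps, seed=config.seed,
        )
        (out / "comparison.json").write_text(
            json.dumps(comparison.__dict__, indent=2) + "\n"
        )
    done(computed=comparison is not None)

    report["outputs"] = {
        p.name: _sha(p) for p in sorted(out.glob("*.csv"))
    }
    (out / "provenance.json").write_text(json.dumps(report, indent=2, default=str) + "\n")
    return report


def _year1_totals(costed: pd.DataFrame, cframe: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-patient year-1 total costs for eligible cases and controls."""
    from .costing import _eligible, _per_patient_values

    out = {}
    for group in ("case", "control"):
        eligible = _eligible(cframe, 1, "all", group)
        if eligible.empty:
            out[group] = np.array([])
            continue
        per = _per_patient_values(costed, eligible, 1, "cost")
        out[group] = per["total"].to_numpy()
    return out
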