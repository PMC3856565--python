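"""Configuration objects for the simulator, the cohort definition and pipeline runs.

All dates are whole calendar days (:class:`datetime.date`); only birth *year*
is carried for patients, following primary-care database convention, and the
exact birthdate is imputed as 1 July of the birth year everywhere ages are
needed.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

AGE_BANDS = ("0-5", "6-17", "18+")
SEXES = ("M", "F")
CATEGORIES = (
    "investigations",
    "primary_care",
    "prescriptions",
    "outpatient",
    "admissions",
)

ADHD_DRUGS = ("dexamfetamine", "methylphenidate", "atomoxetine")


def age_band(age_years: int) -> str:
    """Map an integer age in years onto the reporting bands 0-5, 6-17, >=18."""
    if age_years < 0:
        raise ValueError(f"negative age: {age_years}")
    if age_years <= 5:
        return "0-5"
    if age_years <= 17:
        return "6-17"
    return "18+"


class CountModel(BaseModel):
    """Zero-inflated gamma-Poisson (negative binomial) annual event counts.

    With probability ``p_zero`` the annual count is structurally zero;
    otherwise it is drawn NB with the given mean and dispersion (larger
    ``dispersion`` is closer to Poisson). Means are per fully registered
    year and are scaled by the fraction of the year the patient is present.
    """

    p_zero: float = Field(ge=0.0, le=1.0)
    mean: float = Field(ge=0.0)
    dispersion: float = Field(default=1.0, gt=0.0)


class ResourceIntensity(BaseModel):
    """Annual resource-use count models per category, for cases and non-cases.

    A patient uses the ``case`` model in calendar years from their true onset
    year onward and the ``control`` model before onset (and always, if they
    never develop the condition). Prescription intensity here covers
    non-ADHD items only; ADHD repeat prescriptions are generated separately
    from the treatment model.
    """

    case: dict[str, CountModel]
    control: dict[str, CountModel]

    @model_validator(mode="after")
    def _check_categories(self) -> "ResourceIntensity":
        for side in (self.case, self.control):
            missing = set(CATEGORIES) - set(side)
            if missing:
                raise ValueError(f"resource_intensity missing categories: {sorted(missing)}")
        return self


def _default_intensity() -> ResourceIntensity:
    # Calibrated to the scale of year-1 resource use reported for diagnosed
    # ADHD cases vs matched controls in UK primary care (consultations ~7 vs
    # ~2.4/yr, investigations ~1.3 vs 0.8, outpatient ~2.6 vs 0.4,
    # admissions ~0.1 both). Non-ADHD prescription intensity is similar in
    # both groups; ADHD repeat scripts are added on top for treated cases.
    case = {
        "investigations": CountModel(p_zero=0.70, mean=4.0, dispersion=0.8),
        "primary_care": CountModel(p_zero=0.05, mean=7.0, dispersion=2.0),
        "prescriptions": CountModel(p_zero=0.25, mean=4.0, dispersion=1.0),
        "outpatient": CountModel(p_zero=0.30, mean=3.6, dispersion=1.5),
        "admissions": CountModel(p_zero=0.92, mean=1.3, dispersion=0.7),
    }
    control = {
        "investigations": CountModel(p_zero=0.80, mean=3.8, dispersion=0.8),
        "primary_care": CountModel(p_zero=0.30, mean=3.4, dispersion=1.5),
        "prescriptions": CountModel(p_zero=0.40, mean=4.8, dispersion=0.8),
        "outpatient": CountModel(p_zero=0.85, mean=2.6, dispersion=1.0),
        "admissions": CountModel(p_zero=0.94, mean=1.2, dispersion=0.7),
    }
    return ResourceIntensity(case=case, control=control)


class CostParams(BaseModel):
    """Parameters for generating the synthetic reference-cost schedules."""

    n_other_products: int = Field(default=60, ge=0)
    #: fraction of non-ADHD products that receive an exact (product, year)
    #: price; the remainder must be priced through BNF-level averages.
    p_exact_priced: float = Field(default=0.9, ge=0.0, le=1.0)
    nic_log_mean: float = 2.0  # log £ scale for non-ADHD item costs
    nic_log_sd: float = 0.8
    annual_inflation: float = 0.025  # used to build the index to 2011 prices
    daycase_elective_share: float = Field(default=0.6, ge=0.0, le=1.0)
    procedural_uplift: float = 0.175
    default_outpatient_tariff: float = 120.0
    schedule_year_min: int = 1995
    schedule_year_max: int = 2012


class RegistrationModel(BaseModel):
    """Per-patient registration start/end distributions.

    Start dates are uniform over the recruitment window (clamped to the
    imputed birthdate); the end is the earliest of an exponential
    death time, an exponential transfer-out time, and the database's last
    collection date, applied in that order.
    """

    start_min: dt.date = dt.date(1995, 1, 1)
    start_max: dt.date = dt.date(2008, 12, 31)
    p_death_per_year: float = Field(default=0.002, ge=0.0, le=1.0)
    p_transfer_per_year: float = Field(default=0.03, ge=0.0, le=1.0)


class SimulationConfig(BaseModel):
    """Full parameterisation of the synthetic EHR generator."""

    study_start: dt.date = dt.date(1998, 1, 1)
    study_end: dt.date = dt.date(2010, 12, 31)
    n_practices: int = Field(default=20, ge=1)
    n_patients: int = Field(default=5000, ge=0)
    sex_ratio_male: float = Field(default=0.5, ge=0.0, le=1.0)
    birth_year_min: int = 1960
    birth_year_max: int = 2004
    registration: RegistrationModel = RegistrationModel()
    db_last_collection: dt.date = dt.date(2012, 6, 30)

    #: annual onset hazard per 100,000 by age band and sex
    incidence_truth: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "0-5": {"M": 6.0, "F": 2.0},
            "6-17": {"M": 70.0, "F": 8.0},
            "18+": {"M": 1.2, "F": 1.0},
        }
    )
    p_record_second_diagnosis: float = Field(default=0.9, ge=0.0, le=1.0)
    p_treated: float = Field(default=0.8, ge=0.0, le=1.0)
    drug_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "methylphenidate": 0.80,
            "atomoxetine": 0.15,
            "dexamfetamine": 0.05,
        }
    )
    #: mean of the exponential treatment-persistence time, in years
    mean_treatment_years: float = Field(default=3.0, gt=0.0)
    #: annual narcolepsy hazard per 100,000 (drives the exclusion pathway)
    narcolepsy_rate: float = Field(default=2.0, ge=0.0)
    resource_intensity: ResourceIntensity = Field(default_factory=_default_intensity)
    cost_params: CostParams = CostParams()
    seed: int = 0

    @field_validator("incidence_truth")
    @classmethod
    def _check_truth(cls, v: dict[str, dict[str, float]]) -> dict[str, dict[str, float]]:
        for band in AGE_BANDS:
            if band not in v:
                raise ValueError(f"incidence_truth missing age band {band!r}")
            for sex in SEXES:
                if sex not in v[band]:
                    raise ValueError(f"incidence_truth[{band!r}] missing sex {sex!r}")
                if v[band][sex] < 0:
                    raise ValueError(f"incidence_truth[{band!r}][{sex!r}] negative")
        return v

    @field_validator("drug_mix")
    @classmethod
    def _check_mix(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(ADHD_DRUGS)
        if unknown:
            raise ValueError(f"drug_mix has unknown drugs: {sorted(unknown)}")
        total = sum(v.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"drug_mix proportions sum to {total}, expected 1")
        return v

    @model_validator(mode="after")
    def _check_dates(self) -> "SimulationConfig":
        if self.study_end < self.study_start:
            raise ValueError("study_end before study_start")
        if self.db_last_collection < self.study_start:
            raise ValueError("db_last_collection before study_window")
        if self.birth_year_max < self.birth_year_min:
            raise ValueError("birth_year_max < birth_year_min")
        return self


class CohortDefinition(BaseModel):
    """Code sets and rule parameters for case ascertainment."""

    adhd_code_set: set[str] = Field(default_factory=lambda: {"ADHD"})
    adhd_drug_set: set[str] = Field(default_factory=lambda: set(ADHD_DRUGS))
    exclusion_code_set: set[str] = Field(default_factory=lambda: {"NARC"})
    washin_days: int = Field(default=182, ge=0)
    control_ratio: int = Field(default=3, ge=1)

    @field_validator("adhd_code_set", "adhd_drug_set", "exclusion_code_set")
    @classmethod
    def _non_empty(cls, v: set[str]) -> set[str]:
        if not v:
            raise ValueError("code set must be non-empty")
        return v

    @field_validator("adhd_drug_set")
    @classmethod
    def _known_drugs(cls, v: set[str]) -> set[str]:
        unknown = v - set(ADHD_DRUGS)
        if unknown:
            raise ValueError(f"unknown drug name(s) in adhd_drug_set: {sorted(unknown)}")
        return v


class RunConfig(BaseModel):
    """End-to-end pipeline run configuration."""

    simulation: SimulationConfig = SimulationConfig()
    cohort: CohortDefinition = CohortDefinition()
    #: calendar years for incidence/prevalence reporting
    analysis_years: Optional[list[int]] = None
    #: existing dataset directory; when None the pipeline simulates one
    dataset_dir: Optional[Path] = None
    schedule_dir: Optional[Path] = None
    out_dir: Path = Path("ehrepi_out")
    seed: int = 0
    strict_costing: bool = True
    followup_years: int = Field(default=5, ge=1, le=5)
    bootstrap_reps: int = Field(default=2000, ge=0)
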