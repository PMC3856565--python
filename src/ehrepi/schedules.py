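"""Reference-cost schedules: container, CSV round-trip.

The schedule bundles every tariff table the costing stage needs:

* drug net ingredient cost (NIC) per item by (product, year), with average
  NICs at BNF sub-paragraph, section and chapter level as a fallback ladder;
* an inflation index expressing each calendar year's prices in 2011 pounds;
* primary-care consultation unit costs by (consultation type, staff type),
  quoted either per visit or per hour with an average-duration table;
* investigation tariffs per test plus same-day panel definitions;
* outpatient tariffs by (department, first vs follow-up attendance);
* inpatient admission tariffs by (casemix group code, admission type), with
  the elective/emergency mix used for ambiguous day cases and the fixed
  procedural uplift applied to all admissions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

BNF_LEVELS = ("sub_paragraph", "section", "chapter")

SCHEDULE_FILES = (
    "drug_nic.csv",
    "bnf_averages.csv",
    "inflation.csv",
    "consultation_costs.csv",
    "durations.csv",
    "investigation_tariffs.csv",
    "panels.csv",
    "outpatient_tariffs.csv",
    "admission_tariffs.csv",
    "meta.csv",
)


@dataclass
class Panel:
    panel_id: str
    tests: frozenset[str]
    tariff: float


@dataclass
class CostSchedule:
    """In-memory tariff tables keyed for O(1) lookup."""

    drug_nic: dict[tuple[str, int], float]
    bnf_averages: dict[tuple[str, str, int], float]  # (level, key, year) -> £
    inflation_index: dict[int, float]  # year -> factor to 2011 £
    consultation_costs: dict[tuple[str, str], tuple[str, float]]  # -> (unit, cost)
    duration_minutes: dict[str, float]
    investigation_tariffs: dict[str, float]
    panels: list[Panel]
    outpatient_tariffs: dict[tuple[str, str], float]  # (department, first|follow_up)
    admission_tariffs: dict[tuple[str, str], float]  # (group, elective|emergency)
    daycase_elective_share: float = 0.6
    procedural_uplift: float = 0.175
    default_outpatient_tariff: float = 120.0

    def __post_init__(self) -> None:
        if self.inflation_index and abs(self.inflation_index.get(2011, 1.0) - 1.0) > 1e-9:
            raise ValueError("inflation index must be 1.0 in the 2011 base year")
        if not 0.0 <= self.daycase_elective_share <= 1.0:
            raise ValueError("daycase_elective_share must lie in [0, 1]")
        for mapping in (self.drug_nic, self.bnf_averages, self.investigation_tariffs,
                        self.outpatient_tariffs, self.admission_tariffs):
            for key, value in mapping.items():
                if value < 0:
                    raise ValueError(f"negative tariff for {key!r}")

    # ------------------------------------------------------------------ IO
    def to_dir(self, directory: str | Path) -> None:
        """Write the schedule as the standard set of CSV files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [(p, y, c) for (p, y), c in sorted(self.drug_nic.items())],
            columns=["product", "year", "nic"],
        ).to_csv(directory / "drug_nic.csv", index=False)
        pd.DataFrame(
            [(lv, k, y, c) for (lv, k, y), c in sorted(self.bnf_averages.items())],
            columns=["level", "key", "year", "avg_nic"],
        ).to_csv(directory / "bnf_averages.csv", index=False)
        pd.DataFrame(
            sorted(self.inflation_index.items()), columns=["year", "factor"]
        ).to_csv(directory / "inflation.csv", index=False)
        pd.DataFrame(
            [(t, s, u, c) for (t, s), (u, c) in sorted(self.consultation_costs.items())],
            columns=["consultation_type", "staff_type", "unit", "cost"],
        ).to_csv(directory / "consultation_costs.csv", index=False)
        pd.DataFrame(
            sorted(self.duration_minutes.items()),
            columns=["consultation_type", "minutes"],
        ).to_csv(directory / "durations.csv", index=False)
        pd.DataFrame(
            sorted(self.investigation_tariffs.items()), columns=["test_code", "tariff"]
        ).to_csv(directory / "investigation_tariffs.csv", index=False)
        pd.DataFrame(
            [(p.panel_id, ";".join(sorted(p.tests)), p.tariff) for p in self.panels],
            columns=["panel_id", "test_codes", "tariff"],
        ).to_csv(directory / "panels.csv", index=False)
        pd.DataFrame(
            [(d, o, c) for (d, o), c in sorted(self.outpatient_tariffs.items())],
            columns=["department", "visit_order", "tariff"],
        ).to_csv(directory / "outpatient_tariffs.csv", index=False)
        pd.DataFrame(
            [(g, t, c) for (g, t), c in sorted(self.admission_tariffs.items())],
            columns=["group_code", "admission_type", "tariff"],
        ).to_csv(directory / "admission_tariffs.csv", index=False)
        pd.DataFrame(
            [
                ("daycase_elective_share", self.daycase_elective_share),
                ("procedural_uplift", self.procedural_uplift),
                ("default_outpatient_tariff", self.default_outpatient_tariff),
            ],
            columns=["key", "value"],
        ).to_csv(directory / "meta.csv", index=False)

    @classmethod
    def from_dir(cls, directory: str | Path) -> "CostSchedule":
        """Load a schedule previously written with :meth:`to_dir`."""
        directory = Path(directory)
        missing = [f for f in SCHEDULE_FILES if not (directory / f).exists()]
        if missing:
            raise FileNotFoundError(
                f"schedule directory {directory} is missing: {', '.join(missing)}"
            )
        drug = pd.read_csv(directory / "drug_nic.csv")
        bnf = pd.read_csv(directory / "bnf_averages.csv", dtype={"key": str})
        infl = pd.read_csv(directory / "inflation.csv")
        cons = pd.read_csv(directory / "consultation_costs.csv")
        dur = pd.read_csv(directory / "durations.csv")
        inv = pd.read_csv(directory / "investigation_tariffs.csv")
        pan = pd.read_csv(directory / "panels.csv")
        outp = pd.read_csv(directory / "outpatient_tariffs.csv")
        adm = pd.read_csv(directory / "admission_tariffs.csv")
        meta = dict(pd.read_csv(directory / "meta.csv").itertuples(index=False, name=None))
        return cls(
            drug_nic={(r.product, int(r.year)): float(r.nic) for r in drug.itertuples()},
            bnf_averages={
                (r.level, str(r.key), int(r.year)): float(r.avg_nic) for r in bnf.itertuples()
            },
            inflation_index={int(r.year): float(r.factor) for r in infl.itertuples()},
            consultation_costs={
                (r.consultation_type, r.staff_type): (r.unit, float(r.cost))
                for r in cons.itertuples()
            },
            duration_minutes={r.consultation_type: float(r.minutes) for r in dur.itertuples()},
            investigation_tariffs={r.test_code: float(r.tariff) for r in inv.itertuples()},
            panels=[
                Panel(r.panel_id, frozenset(str(r.test_codes).split(";")), float(r.tariff))
                for r in pan.itertuples()
            ],
            outpatient_tariffs={
                (r.department, r.visit_order): float(r.tariff) for r in outp.itertuples()
            },
            admission_tariffs={
                (r.group_code, r.admission_type): float(r.tariff) for r in adm.itertuples()
            },
            daycase_elective_share=float(meta["daycase_elective_share"]),
            procedural_uplift=float(meta["procedural_uplift"]),
            default_outpatient_tariff=float(meta["default_outpatient_tariff"]),
        )
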