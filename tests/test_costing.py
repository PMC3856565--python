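"""Unit-cost attribution: BNF fallback ladder, panel grouping, admission
uplift, follow-up windows and summary linearity."""

from __future__ import annotations

import datetime as dt
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from conftest import d
from ehrepi import (
    UnpriceableEventError,
    cost_admission,
    cost_consultation,
    cost_investigations,
    cost_outpatient,
    cost_prescription,
    group_tests_into_panels,
    observation_complete_for_year,
    resource_use_summary,
    summarize_annual_costs,
)
from ehrepi.costing import CostingReport
from ehrepi.schedules import CostSchedule


def rx(product, date="2005-05-05", bnf="2.1.1", pid=1):
    return SimpleNamespace(patient_id=pid, date=d(date), product=product, bnf_code=bnf)


# --------------------------------------------------------------------------
# prescriptions: exact match and BNF ladder
# --------------------------------------------------------------------------

def test_exact_nic_times_inflation(toy_schedule):
    ev = cost_prescription(rx("drugX"), toy_schedule)
    assert ev.cost == pytest.approx(12.50 * 1.20)
    assert ev.attribution_level == "exact"


def test_fallback_ladder_degrades_one_level_per_ablation(toy_schedule):
    """Deleting the price at each level moves attribution exactly one step
    down the ladder, and the cost becomes the recorded average."""
    item = rx("unknown_product")
    ev = cost_prescription(item, toy_schedule)
    assert (ev.attribution_level, ev.cost) == ("sub_paragraph", pytest.approx(8.0 * 1.2))

    del toy_schedule.bnf_averages[("sub_paragraph", "2.1.1", 2005)]
    ev = cost_prescription(item, toy_schedule)
    assert (ev.attribution_level, ev.cost) == ("section", pytest.approx(9.5 * 1.2))

    del toy_schedule.bnf_averages[("section", "2.1", 2005)]
    ev = cost_prescription(item, toy_schedule)
    assert (ev.attribution_level, ev.cost) == ("chapter", pytest.approx(11.0 * 1.2))

    del toy_schedule.bnf_averages[("chapter", "2", 2005)]
    with pytest.raises(UnpriceableEventError, match="2.1.1"):
        cost_prescription(item, toy_schedule)


def test_exact_entry_ablation_changes_cost_to_recorded_average(toy_schedule):
    before = cost_prescription(rx("drugX"), toy_schedule)
    del toy_schedule.drug_nic[("drugX", 2005)]
    after = cost_prescription(rx("drugX"), toy_schedule)
    assert before.attribution_level == "exact"
    assert after.attribution_level == "sub_paragraph"
    assert after.cost == pytest.approx(8.0 * 1.2)
    assert after.cost != before.cost


def test_inflation_covariance_drugs_only(toy_schedule):
    """Doubling every inflation factor doubles prescription costs and leaves
    all other categories untouched."""
    base_rx = cost_prescription(rx("drugX"), toy_schedule).cost
    cons = SimpleNamespace(patient_id=1, date=d("2005-05-05"),
                           consultation_type="surgery", staff_type="gp")
    base_cons = cost_consultation(cons, toy_schedule).cost
    adm = SimpleNamespace(patient_id=1, date=d("2005-05-05"),
                          group_code="G01", admission_type="elective")
    base_adm = cost_admission(adm, toy_schedule).cost

    toy_schedule.inflation_index = {y: 2 * f for y, f in toy_schedule.inflation_index.items()}
    toy_schedule.inflation_index[2011] = 1.0  # container invariant on reload only
    assert cost_prescription(rx("drugX"), toy_schedule).cost == pytest.approx(2 * base_rx)
    assert cost_consultation(cons, toy_schedule).cost == pytest.approx(base_cons)
    assert cost_admission(adm, toy_schedule).cost == pytest.approx(base_adm)


# --------------------------------------------------------------------------
# consultations
# --------------------------------------------------------------------------

def test_per_visit_and_per_hour_consultations(toy_schedule):
    surgery = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                              consultation_type="surgery", staff_type="gp")
    assert cost_consultation(surgery, toy_schedule).cost == pytest.approx(36.0)
    clinic = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                             consultation_type="clinic", staff_type="gp")
    # £140/hour x 11.7 minutes
    assert cost_consultation(clinic, toy_schedule).cost == pytest.approx(27.30)


def test_zero_duration_type_costs_nothing_with_warning(toy_schedule):
    report = CostingReport()
    visit = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                            consultation_type="drop_in", staff_type="nurse")
    ev = cost_consultation(visit, toy_schedule, report)
    assert ev.cost == 0.0
    assert report.n_zero_duration == 1


def test_unknown_consultation_pair_is_unpriceable(toy_schedule):
    bad = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                          consultation_type="video", staff_type="gp")
    with pytest.raises(UnpriceableEventError):
        cost_consultation(bad, toy_schedule)


# --------------------------------------------------------------------------
# investigations and panels
# --------------------------------------------------------------------------

def _day(codes, date="2005-03-03", pid=1):
    return pd.DataFrame(
        {"patient_id": pid, "date": d(date), "test_code": list(codes)}
    )


def test_panel_substitution_and_same_day_condition(toy_schedule):
    ev = cost_investigations(_day(["A", "B"]), toy_schedule)
    assert ev.cost == pytest.approx(5.0)  # panel, not 4 + 3
    a = cost_investigations(_day(["A"], "2005-03-03"), toy_schedule)
    b = cost_investigations(_day(["B"], "2005-03-04"), toy_schedule)
    assert a.cost + b.cost == pytest.approx(7.0)


def test_largest_panel_first(toy_schedule):
    total, parts = group_tests_into_panels(["A", "B", "C"], toy_schedule)
    assert parts == ["PAN_ABC"]
    assert total == pytest.approx(9.0)


def test_unknown_test_code_is_unpriceable(toy_schedule):
    with pytest.raises(UnpriceableEventError):
        cost_investigations(_day(["A", "ZZZ"]), toy_schedule)


def brute_force_groupings(codes, schedule):
    """Every achievable total over all valid panel applications."""
    totals = set()

    def rec(remaining, acc):
        applied_any = False
        for panel in schedule.panels:
            if all(remaining.count(t) >= 1 for t in panel.tests):
                nxt = list(remaining)
                for t in panel.tests:
                    nxt.remove(t)
                rec(nxt, acc + panel.tariff)
                applied_any = True
        # also allow stopping panels here and pricing the rest individually
        totals.add(acc + sum(schedule.investigation_tariffs[c] for c in remaining))
        return applied_any

    rec(list(codes), 0.0)
    return totals


def test_greedy_total_is_achievable_and_never_exceeds_individual_sum(toy_schedule):
    rng = np.random.default_rng(8)
    codes_pool = list(toy_schedule.investigation_tariffs)
    for _ in range(50):
        day = [codes_pool[i] for i in rng.integers(0, len(codes_pool),
                                                   rng.integers(1, 7))]
        total, _parts = group_tests_into_panels(day, toy_schedule)
        individual = sum(toy_schedule.investigation_tariffs[c] for c in day)
        assert total <= individual + 1e-9
        assert any(abs(total - t) < 1e-9 for t in brute_force_groupings(day, toy_schedule))


# --------------------------------------------------------------------------
# outpatient and admissions
# --------------------------------------------------------------------------

def test_outpatient_tariff_lookup_and_default(toy_schedule):
    report = CostingReport()
    first = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                            department="paediatrics", visit_order="first")
    follow = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                             department="paediatrics", visit_order="follow_up")
    unknown = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                              department="dermatology", visit_order="first")
    assert cost_outpatient(first, toy_schedule).cost == 250.0
    assert cost_outpatient(follow, toy_schedule).cost == 150.0
    assert cost_outpatient(unknown, toy_schedule, report).cost == 120.0
    assert report.n_default_outpatient == 1


def test_admission_uplift_and_daycase_mix(toy_schedule):
    elective = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                               group_code="G01", admission_type="elective")
    assert cost_admission(elective, toy_schedule).cost == pytest.approx(1175.0)
    ambiguous = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                                group_code="G02", admission_type="daycase_ambiguous")
    # 0.6 x 800 + 0.4 x 1200 = 960; x 1.175 = 1128
    assert cost_admission(ambiguous, toy_schedule).cost == pytest.approx(1128.0)
    toy_schedule.procedural_uplift = 0.0
    assert cost_admission(elective, toy_schedule).cost == pytest.approx(1000.0)


def test_unknown_admission_group_is_unpriceable(toy_schedule):
    bad = SimpleNamespace(patient_id=1, date=d("2005-01-01"),
                          group_code="G99", admission_type="elective")
    with pytest.raises(UnpriceableEventError):
        cost_admission(bad, toy_schedule)


# --------------------------------------------------------------------------
# follow-up windows
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "censor_days,k,complete",
    [
        (400, 1, True),
        (400, 2, False),
        (730, 2, True),
        (729, 2, False),
        (364, 1, False),
        (365, 1, True),
        (1825, 5, True),
    ],
)
def test_complete_year_rule(censor_days, k, complete):
    index = d("2005-01-01")
    end = index + dt.timedelta(days=censor_days)
    assert observation_complete_for_year(end, index, k) is complete


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

def _cohort(rows):
    return pd.DataFrame(
        rows,
        columns=["patient_id", "group", "index_date", "age_band", "observation_end"],
    )


def _events(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "date", "category", "cost", "attribution_level"]
    )


def test_total_is_exact_sum_of_categories_and_means_are_linear():
    index = d("2005-01-01")
    cohort = _cohort([
        (1, "case", index, "6-17", d("2010-01-01")),
        (2, "case", index, "6-17", d("2010-01-01")),
    ])
    events = _events([
        (1, d("2005-02-01"), "investigations", 10.0, "n/a"),
        (1, d("2005-02-01"), "primary_care", 200.0, "n/a"),
        (1, d("2005-03-01"), "prescriptions", 300.0, "exact"),
        (2, d("2005-02-01"), "investigations", 12.0, "n/a"),
        (2, d("2005-04-01"), "outpatient", 500.0, "n/a"),
        (2, d("2005-05-01"), "admissions", 1000.0, "n/a"),
    ])
    s = summarize_annual_costs(events, cohort, 1, "all", "case")
    assert s.n == 2
    cat_means = [s.stats[c]["mean"] for c in
                 ("investigations", "primary_care", "prescriptions",
                  "outpatient", "admissions")]
    assert s.stats["total"]["mean"] == pytest.approx(sum(cat_means))
    assert s.stats["total"]["mean"] == pytest.approx((510 + 1512) / 2)


def test_events_outside_window_and_index_day_are_excluded():
    index = d("2005-01-01")
    cohort = _cohort([(1, "case", index, "6-17", d("2010-01-01"))])
    events = _events([
        (1, index, "primary_care", 100.0, "n/a"),                      # day 0
        (1, index + dt.timedelta(days=1), "primary_care", 40.0, "n/a"),   # day 1
        (1, index + dt.timedelta(days=365), "primary_care", 50.0, "n/a"), # day 365
        (1, index + dt.timedelta(days=366), "primary_care", 60.0, "n/a"), # year 2
    ])
    y1 = summarize_annual_costs(events, cohort, 1, "all", "case")
    assert y1.stats["total"]["mean"] == pytest.approx(90.0)
    y2 = summarize_annual_costs(events, cohort, 2, "all", "case")
    assert y2.stats["total"]["mean"] == pytest.approx(60.0)


def test_patient_with_no_events_contributes_zero():
    cohort = _cohort([(1, "case", d("2005-01-01"), "6-17", d("2010-01-01"))])
    s = summarize_annual_costs(_events([]), cohort, 1, "all", "case")
    assert s.n == 1
    assert s.stats["total"]["mean"] == 0.0
    assert s.stats["total"]["median"] == 0.0


def test_empty_group_is_flagged_not_zero():
    cohort = _cohort([(1, "case", d("2005-01-01"), "6-17", d("2005-03-01"))])
    s = summarize_annual_costs(_events([]), cohort, 1, "all", "case")  # ineligible
    assert s.n == 0
    assert s.stats is None


def test_resource_use_counts_match_brute_force_tally():
    index = d("2005-01-01")
    cohort = _cohort([
        (1, "case", index, "6-17", d("2010-01-01")),
        (2, "case", index, "6-17", d("2010-01-01")),
    ])
    rows = []
    rng = np.random.default_rng(3)
    cats = ["prescriptions", "primary_care", "outpatient"]
    for pid in (1, 2):
        for _ in range(int(rng.integers(0, 15))):
            rows.append((pid, index + dt.timedelta(days=int(rng.integers(0, 800))),
                         cats[rng.integers(0, 3)]))
    events = pd.DataFrame(rows, columns=["patient_id", "date", "category"])
    s = resource_use_summary(events, cohort, 1, "all", "case")
    for cat in cats:
        tallies = [
            sum(1 for p, dd, c in rows
                if p == pid and c == cat and 1 <= (dd - index).days <= 365)
            for pid in (1, 2)
        ]
        assert s.stats[cat]["mean"] == pytest.approx(np.mean(tallies))


def test_nine_prescriptions_in_year_one_counts_nine():
    index = d("2005-01-01")
    cohort = _cohort([(1, "case", index, "6-17", d("2010-01-01"))])
    events = pd.DataFrame(
        [(1, index + dt.timedelta(days=10 * (i + 1)), "prescriptions")
         for i in range(9)],
        columns=["patient_id", "date", "category"],
    )
    s = resource_use_summary(events, cohort, 1, "all", "case")
    assert s.stats["prescriptions"]["mean"] == 9.0


def test_direction_recovery_case_costs_exceed_control(small_dataset, small_schedule, defn):
    """Cases are generated with heavier resource use than controls, so the
    case/control mean-total ratio must exceed 1 in every follow-up year."""
    from ehrepi import build_cohort, cohort_frame, cost_events

    result = build_cohort(small_dataset.patients, small_dataset.diagnoses,
                          small_dataset.prescriptions, defn, seed=0)
    if result.cases.empty or result.controls.empty:
        pytest.skip("no cases in the small fixture")
    costed, _ = cost_events(small_dataset, small_schedule)
    cframe = cohort_frame(result, small_dataset.patients)
    checked = 0
    for k in range(1, 6):
        case = summarize_annual_costs(costed, cframe, k, "all", "case")
        ctrl = summarize_annual_costs(costed, cframe, k, "all", "control")
        if case.stats is None or ctrl.stats is None or ctrl.stats["total"]["mean"] == 0:
            continue
        assert case.stats["total"]["mean"] > ctrl.stats["total"]["mean"]
        checked += 1
    assert checked >= 1
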