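# Methods

This note documents the models and conventions behind `ehrepi`: what the
synthetic generator emulates, how each estimator is defined at the day
level, and the design choices made where the underlying procedures are
conventionally underspecified.

## Data model

The unit of observation is a registration spine row per patient —
practice, sex, birth **year** (no full birthdate, following primary-care
database convention), registration start/end, optional death and
transfer-out dates — plus five dated event tables: diagnoses (coded),
prescriptions (product + BNF code), consultations (primary-care contacts
and outpatient attendances in one table, distinguished by consultation
type), laboratory/diagnostic tests, and hospital admissions (pre-grouped
casemix code + admission type). All dates are whole calendar days; there is
no within-day ordering beyond a stable sort by (patient, date, attribute).

Because only birth year is stored, the birthdate is imputed as **1 July of
the birth year** for all age arithmetic. The mid-year imputation minimises
systematic age bias and makes "age attained on 1 July of calendar year y"
equal to `y − birth_year` exactly. Age bands are 0–5, 6–17 and ≥18,
chosen because licensing and guidance for ADHD medicines change at ages
6 and 18.

## Synthetic generator

The generator is first-class, tested code: its role is to produce datasets
with *known* epidemiology and cost structure so every downstream stage can
be validated by parameter recovery.

* **Registration.** Start dates are uniform over a recruitment window
  (clamped at the imputed birthdate); the end is the earliest of an
  exponential death time, an exponential transfer-out time and the
  database's last collection date, applied in that order (death ≤
  transfer-out ≤ truncation). Defaults: death hazard 0.002/yr, transfer
  0.03/yr, collection horizon 30 June 2012.
* **Onset.** ADHD onset is a discrete-time hazard process over calendar
  years: within each registered year the onset probability is
  `h(band, sex)/10⁵ × days_registered/365.25`, with the band taken at
  mid-year; the first hit wins and the onset day is uniform over the
  registered part of the year. Default hazards (per 100,000/yr) are
  6–17: 70 (M) / 8 (F); 0–5: 6/2; ≥18: 1.2/1.0 — the scale and ~10:1
  male-to-female ratio observed for diagnosed ADHD in UK primary care.
* **Records at onset.** A first ADHD diagnosis is written on the onset day;
  a confirmatory second diagnosis follows after 30–182 days (probability
  `p_record_second_diagnosis`, default 0.9), truncated at the censor date.
  With probability `p_treated` (default 0.8) the patient starts a drug from
  the configured mix (methylphenidate 0.80 / atomoxetine 0.15 /
  dexamfetamine 0.05, BNF 4.4.0) 0–60 days after onset and receives 28-day
  repeat prescriptions for an exponential persistence time (default mean
  3 years). Narcolepsy codes arise independently at a small hazard
  (2/100,000/yr) to drive the exclusion pathway.
* **Resource use.** Annual event counts per category are zero-inflated
  gamma-Poisson (negative binomial), scaled by the fraction of the year
  registered, with separate case (post-onset years) and non-case
  parameters. Defaults are calibrated to the year-1 resource-use scale
  reported for diagnosed-ADHD cases vs matched controls in UK primary care
  (consultations ≈7 vs ≈2.4/yr, investigations ≈1.3 vs 0.8, outpatient
  ≈2.6 vs 0.4, admissions ≈0.1 both; non-ADHD prescribing similar between
  groups). The zero-inflated count shape is an assumption — the source
  distributions are only known to be right-skewed — and is configurable.
* **Streams.** Every table draws from its own random stream spawned from
  the master seed, so enlarging one table never reshuffles another, and a
  fixed config reproduces bit-for-bit.

What the generator does **not** emulate: real Read/ICD code dictionaries,
clinically coherent non-ADHD morbidity, free-text, secondary-care
prescribing, regional structure, or calendar trends in recording practice.
Passing recovery tests therefore demonstrates the correctness of the
estimators under the stated generative assumptions, not the realism of any
particular rate for the UK population.

## Cohort construction

Two qualifying routes: ≥2 ADHD diagnoses ever, or ≥1 diagnosis plus ≥1
ADHD-drug prescription; a single diagnosis alone never qualifies (it may be
provisional). The index date is `min(first diagnosis, first prescription)`.
Pemoline and modafinil are deliberately not in the drug set.

Exclusions are applied in a fixed order so logs are deterministic:
narcolepsy history (any time, before or after index) first, then wash-in.
"Six months" of wash-in is fixed at 182 days and the boundary is
inclusive — exactly 182 days of prior registration is retained. Wash-in is
evaluated against prior registration time only.

Controls are sampled uniformly without replacement from patients with no
ADHD diagnosis and no ADHD prescription, within the exact
(birth year, sex, practice) cell, shared across the cell's cases; the
default ratio is 3 with shortfall allowed and logged. Each control inherits
its case's index date as a **pseudo-index** to anchor costing windows — the
source procedures are silent on this, and inheritance is the choice that
makes case and control observation windows commensurable.

## Person-time, incidence, prevalence

The person-time ledger assigns each patient at-risk days per calendar year:
from registration start to the earliest of registration end (death,
transfer, collection truncation) and the day **before** presentation — the
presentation day itself is not at risk, since the patient is a case on that
date. Days convert to years with divisor 365.25; leap days are counted
literally. A brute-force per-day loop with identical conventions serves as
the oracle in tests and must agree exactly.

Age is attributed by the band attained on 1 July of the calendar year,
applied to the whole year's days, for numerators and denominators alike
(and by the generator's hazard), so stratified recovery is unbiased by
construction and stratified person-years sum exactly to the all-ages total.
Whether the source analyses attributed age dynamically within a year is
unknown; the mid-year convention avoids splitting intervals at imputed
birthdays.

Treated incidence replaces the presentation event with the first-ever
ADHD-drug prescription, over the same denominator.

Prevalence at 1 July of year *t* requires presentation strictly before,
a last ADHD record (diagnosis or prescription, whichever is later)
strictly after, and registration covering the date ("registered on 1 July"
is read as current registration). Years with ≤12 months between 1 July and
the last collection date raise a washout refusal rather than returning a
biased zero-ish value, and series rendering keeps refused years visibly
"not computed", never 0.

Display precision follows epidemiological convention: rates to 1 decimal
per 100,000, percent changes (vs the series' first year) to integers,
rounded half away from zero.

## Costing

* **Prescriptions** — exact (product, year) NIC, else average NIC at BNF
  sub-paragraph, then section, then chapter, for the prescription's
  calendar year; the result is multiplied by the inflation factor to 2011
  pounds. Only drug costs are inflation-adjusted; all other tariffs are
  used as published in their schedules. The attribution level is recorded,
  and an ablation test verifies that deleting a level degrades attribution
  exactly one step.
* **Consultations** — per-visit costs used directly; per-hour costs
  converted by the average duration for the consultation type (zero
  duration yields £0 with a logged warning).
* **Investigations** — all of a patient's same-day tests are grouped
  greedily, largest defined panel first with lexicographic tie-break;
  leftovers priced individually. Greedy is deterministic and never exceeds
  the individual-tariff sum; a brute-force enumeration oracle confirms the
  result is always an achievable grouping.
* **Outpatient** — (department, first vs follow-up) tariff; unknown
  departments fall back to a configured default and are counted.
* **Admissions** — (group, type) tariff; ambiguous day cases priced at the
  configured elective/emergency mix; every admission is multiplied by
  1 + uplift with uplift 0.175, compensating for missing procedure detail.

Follow-up year *k* covers days 365(k−1)+1 … 365k after index (leap days
ignored for windowing; the index day itself is in no window). A patient
enters the year-k summary only if observation extends through day 365k —
censoring exactly on day 365k counts as complete. The same rule is applied
to year 1, where the source phrasing is ambiguous; events of ineligible
patient-years are dropped entirely. Per patient-year the total is the exact
sum of the five category costs, so mean(total) equals the sum of category
means up to display rounding — the linearity the acceptance checks rely on.
Unpriceable events abort in strict mode or are skipped and counted in
lenient mode.

Cost comparison uses Welch's unequal-variance t test together with a
seeded bootstrap p-value for the mean difference (groups recentred on the
pooled mean, resampled with replacement), reported side by side because
cost distributions are strongly right-skewed; no distributional test was
named by the source, so both are labelled.

## Verification harness sizes

The recovery checks are sized so Monte-Carlo error is bounded but runtimes
stay in seconds: the test suite uses ≈55,000 person-years (5,000 boys
followed 11 years) for hazard recovery at 80/100,000 with a 95% Poisson
interval, and 12,000 adults for prevalence recovery against the closed-form
cumulative risk with a 95% binomial interval; the acceptance script scales
these to 550,000 person-years and 40,000 adults. The prevalence recovery
configuration uses an effectively non-ceasing treatment persistence
(mean 10,000 years) because its closed-form oracle assumes cases remain
record-active; with finite persistence a small fraction of cases stop
treatment before the mid-year point and are correctly not counted by the
bracketing rule.

## Known limitations

* Costs carry the synthetic schedules' currency scale; case/control cost
  *direction* and structure are recovered, but absolute magnitudes are not
  calibrated to any published cost level.
* Confidence intervals for rates and age-standardisation are out of scope.
* The HRG-style admission grouper is not reimplemented; admissions arrive
  with a pre-assigned group code.
* Matching is exact-cell only; no caliper or distance matching.
* `cost_events` prices events for all patients, not only cohort members;
  summaries then restrict to the cohort. This is wasteful but keeps the
  costing stage independent of cohort definitions.
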