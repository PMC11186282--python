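# Methods

This note documents the definitions, numerical choices and modelling
assumptions behind `icuamc`, and what the synthetic-cohort tests do and do
not establish about behaviour on real data.

## Units of analysis

**Admission.**  One ICU stay with admit/discharge timestamps at second
precision.  Timestamps without a timezone are wall-clock local clinical time;
no DST adjustment is applied, because the day-of-therapy metrics are defined
on calendar dates and clinical practice reads the ward clock.

**Episode.**  Admissions of one patient whose discharge→admission gap is
*strictly* less than 48 hours merge into one episode; a gap of exactly 48 h
starts a new episode (the boundary is configurable, `gap_threshold_hours`).
Member admissions are never fused: doses always attribute to the administering
admission's unit, which keeps unit-level consumption additive.  The gap
between discharge and readmission contributes neither length of stay nor
patient-days — only ICU care time divides consumption.  The gap is measured
discharge→admission; episode severity (SAPS 3, EMR) is taken from the first
member admission, ICU death is true if any member ends in ICU death, and
30-day status comes from the last member.  Admissions overlapping an earlier
one of the same patient are rejected as data errors, not reconciled.

**Patient-day.**  Duration of care in hours divided by 24, kept fractional
end to end; rounding happens only at the printing edge of reports.

## Metric definitions and omission rules

DOT counts distinct (admission, calendar date, ATC code) triples; LOT counts
distinct (admission, date) pairs; both use the dose's wall-clock date (a dose
clamped back into the admission interval at ingest uses its clamped date).
Combination products carry one ATC code and count as one agent.  The
surveilled set is exactly the registry's membership (systemic antibacterials
and antifungals); doses with codes outside it are ignored by the metrics and
surfaced in the data-quality report.

Administered DDD divides the administered mass by the route-specific WHO DDD.
Two omission rules follow the source system's behaviour: drugs with no
defined DDD (e.g. sulfamethoxazole/trimethoprim) and amounts denominated in
million units against a mass-denominated index value (colistin) contribute to
DOT and LOT but are excluded from DDD sums; the DOT share so excluded is
reported rather than silently dropped.  The bundled registry deliberately
carries colistin with a mass-denominated DDD so MU-charted doses are
unconvertible, mirroring the surveilled system; a site that charts colistin
in MU against an MU-denominated index can replace the registry file.

Rates are totals divided by patient-days times 1000, undefined (absent, never
zero) on an empty denominator, as is DOT/LOT when LOT = 0.  Printed
precision follows surveillance convention: rates per 1000 patient-days round
half-up to integers; percentages to one decimal in the population table and
to integers in exposure tables.

## Ingest tolerances

Signing delays are routine in electronic records, so a dose stamped outside
its admission interval is clamped to the interval edge and kept; the warning
code distinguishes deviations within the configurable tolerance (default 1 h)
from larger ones.  Nothing is dropped for timing alone; only doses whose
admission cannot be found are rejected.  Unknown referring-clinic labels map
to the explicit `other` stratum with a warning.

## Exposure and outcomes

Exposure is graded at episode scope by the number of distinct drug *classes*
(not agents) ever administered: none / one / two / three / more-than-three.
The class map lives in the registry (decided at ATC 4th level with explicit
overrides, e.g. 2nd- vs 3rd-generation cephalosporins split within J01D) and
is user-replaceable.  The length-of-stay split uses a strict boundary:
"longer than 48 hours" means los_days > 2.0 exactly.

Exposure–mortality summaries report, per level, the mean predicted mortality
(SAPS 3 EMR) with a normal-approximation 95% CI (mean ± 1.96·SE) and the
observed ICU and 30-day proportions.  Episodes missing an EMR or 30-day
status are omitted (no imputation) and counted.  Because published mortality
denominators are sometimes admissions and sometimes episodes, the population
table prints both variants.

## Trend model

The daily series holds, per calendar date, summed DOT and fractional occupied
bed-days; the rate is absent on unoccupied dates.  The trend is an
unpenalized least-squares cubic regression spline of the daily rate on time:
8 interior knots (configurable) at empirical quantiles of the dates carrying
a defined rate, B-spline basis from scipy, coefficients, covariance and
pointwise 95% band from an ordinary least-squares fit (statsmodels).  The
response is Gaussian on the rate scale — the curve smooths the quantity as
plotted rather than modelling counts — and the fit needs at least
`n_knots + 4` dates with a defined rate.  Because the basis reproduces
polynomials up to cubic, a constant series yields an exactly flat fit and a
cubic generating curve is recovered up to noise; both are tested.

## Reports

Every printed rate is derived from the same per-admission totals frame the
metrics module produces; reports never re-derive from raw doses, so stratified
tables conserve grand totals by construction.  Per-clinic DOT rates carry a
nonparametric bootstrap 95% CI (resampling admissions within clinic, default
1000 seeded resamples, percentile interval).  The three-metric comparison
contrasts DOT, administered DDD and pharmacy-dispensed DDD per drug; shelf
stock is converted with the parenteral DDD, and a configurable
dispensed/administered ratio threshold (default 1.5) flags drugs whose shelf
consumption overstates bedside use — the classic pattern for surgical
prophylaxis drugs whose shelf also serves patients outside the surveilled
population.  When under-18 admissions are present in the source data their
patient-days are added to the dispensed-rate denominator and their count is
echoed in the report, since the shelf served them too; the secondary-care
units aggregate into one stratum by default.  Rendering is deterministic
given a seed, and every file carries a provenance header (tool version,
configuration hash).

## Synthetic cohort generator

The generator emulates a four-year, three-unit general-ICU cohort in a
low-consumption setting.  Its default configuration is produced by
`calibrate_to_paper(REFERENCE_COHORT)`, which inverts closed-form summaries:

* care-level and referring-clinic mix from admission counts;
* length of stay per (care level, clinic) as log-normal with
  μ = ln(median), σ = ln(q75/q25)/(2·0.6745); clipped to 2 h–60 d;
* age as a split normal matched to the median and asymmetric IQR
  (65, IQR 48–75), with a 12% under-18 fraction;
* SAPS 3 per care level as a discretized normal matched to median and IQR;
  EMR = logistic(0.115·(SAPS3 − centre)) with the centre solved so the EMR
  median matches its target (0.14 tertiary, 0.08 secondary);
* 30-day death drawn as Bernoulli(EMR) per patient, ICU death as a fixed
  fraction (0.44) of 30-day deaths;
* readmission gaps log-normal around 30 h so both sides of the 48-h merge
  boundary occur; occasional transfers switch care level at small gaps;
* prescribing as per-class course starts: a day-0 empiric start whose
  probability scales with clinic intensity and (LOS/1.4 d)^0.5 — longer
  stays are likelier to be treated, which is what makes therapy length per
  *treated* admission exceed the average stay — plus a daily class-start
  hazard thereafter; course durations 1 + Poisson(6) days truncated at
  discharge; class weights per care level set so 3rd-generation
  cephalosporins dominate tertiary and piperacillin/tazobactam secondary
  consumption; doses fall at nursing-round hours (06/12/18/≈24 ± 18 min
  jitter) to exercise calendar-day boundaries;
* 6‰ of doses have their ATC code blanked to exercise the missing-linkage
  path; two epidemic waves (spring 2020, spring 2021) add a daily overlay
  count and damp prescribing by 20%;
* quarterly dispensing equals administered mass times ≈1.25 with noise, and
  ×3 for cloxacillin, seeding the divergence flag.

The prescribing intensities were calibrated once against the reference
consumption summaries (≈1261/1177 DOT per 1000 patient-days, 66%/47% of
admissions exposed, LOT per admission 3.3/2.1) and then frozen; the remaining
parameters come from the closed-form inversions above.

Alongside the CSVs the generator writes `truth.json`: per-admission DOT, LOT,
DDD and class sets, and per-episode membership and exposure level, enumerated
at generation time by the generator's *own* code path (its own registry
parse, unit conversion and gap grouping, no imports from the metrics or
episodes modules).  This makes it an independent oracle: the test suite
requires the pipeline to reproduce truth.json exactly on cohorts of more than
a thousand episodes.

**What the generator does not model** — and hence what passing tests do not
establish about real data: microbiology and infection diagnoses, escalation
or de-escalation sequencing within a course, correlation between severity and
prescribing beyond the LOS coupling, seasonal case-mix other than the two
waves, inter-hospital referral dynamics, and documentation artefacts beyond
missing ATC codes and late signing.  Episode merging is only exercised for
gaps the gap distribution produces, which is why the episode rule is
additionally tested against an exhaustive pairwise-gap oracle on adversarial
gap sets that include the exact 48-h boundary.

## Problem sizes in the test suite

The suite runs the full pipeline at several scales chosen to make each check
statistically meaningful at interactive runtimes: a 400-patient cohort for
shared fixtures, 20 independent 40-patient cohorts for conservation laws,
≈1300 patients (>1000 episodes) for oracle equivalence, and ≈6000 patients
(>5000 episodes) for mortality-calibration recovery, where each exposure
level's observed mortality must sit within three standard errors of its mean
predicted EMR.  The acceptance script regenerates the full reference-scale
cohort (5190 patients, 2018–2021) in a few seconds.

## Known limitations

* The WHO index is licensed data, so the bundled registry is a curated
  ~40-agent ICU formulary, not the full index; codes outside it are treated
  as non-surveilled.
* DDD route matching falls back to classification-only (no DDD) when a dose's
  route has no index row, which is conservative but can under-count DDD for
  unusual routes.
* The exact mechanism by which under-18 admissions should adjust the
  dispensing comparison is not standardised; the implemented
  denominator-widening is one declared, configurable choice.
* Calendar-day DOT is sensitive to midnight-straddling dosing schedules by
  definition; this is a property of the metric, not of the implementation.
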