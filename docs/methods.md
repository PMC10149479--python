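# Methods

This package implements a claims-based analysis of antiretroviral-therapy
(ART) adherence and viral suppression in people living with HIV, of the
kind run on private-insurer reimbursement data: adherence is measured
from pharmacy refills, mental-health exposure from ICD-10 diagnosis
claims, and outcomes from routine viral-load results. Because such data
are access-restricted, the canonical input is a synthetic cohort with
planted ground truth; every estimator is validated by parameter
recovery.

## Cohort construction

Baseline is the first ART pharmacy claim (ATC prefixes J05AR, J05AG,
J05AE, J05AJ, J05AX; single-NRTI J05AF claims deliberately do not
qualify, and the prefix list is configurable). Follow-up ends at the
earliest of insurance cover end, death, or database closure
(configurable; default 2020-06-30). Filters: non-missing sex and birth
date; age ≥ 15 years at baseline; "on ART for at least 6 months"
operationalised as ≥ 2 ART claims and ≥ 183 days of follow-up. The three
analyses each add one requirement — ≥ 365 days of follow-up
(adherence-factors), ≥ 1095 days (trajectories), ≥ 1 viral-load result
(suppression). Filtering is idempotent and emits an exclusion-flow
report.

## Continuous medication availability (CMA)

Each claim's supply duration is dispensed pills divided by the assumed
adult maintenance dose (a shipped, overridable defined-daily-dose table
keyed by ATC prefix). Supply chains through refill intervals with
unbounded stockpiling: surplus from early refills carries into later
intervals (a cap is available for sensitivity analyses). The daily
adherence value of an interval between consecutive refills — or between
the last refill and follow-up end — is days covered divided by interval
length; windowed CMA averages daily values over consecutive calendar
windows of 1, 3, 6 or 12 months (day-of-month clamped at month ends;
half-open day ranges; trailing short windows dropped, not rescaled).
Non-adherence is CMA strictly below a threshold (80% primary; 70% and
90% sensitivity).

Multi-drug regimens keep one supply inventory per distinct ATC code so
parallel dispensing does not multiply-count supply; per-stream smoothed
daily values combine by per-day maximum ("pooled" mode merges all claims
into one inventory). Smoothing-then-maximum was chosen over
maximum-then-smoothing because it keeps the per-stream interval
arithmetic exact; the test suite's day-walk oracle applies the same
composition rule.

Two plausible-sounding invariants are *not* true under interval-mean
smoothing and are deliberately not asserted: adding a claim can lower
the daily values after the insertion point (a tiny top-up claim late in
a long interval splits it, concentrating the mean early), and moving the
follow-up end re-smooths the final interval, changing windows that
overlap it. The properties actually guaranteed — and tested — are
conservation (covered days + leftover carryover ≤ dispensed supply),
total-coverage monotonicity when claims are added, invariance of windows
that lie entirely before the last refill under truncation, and scale
invariance in (pills, dose).

## Trajectory clustering

Patients with ≥ 12 observed quarters contribute their first 20 quarterly
CMA values; missing tails are filled with the patient's own observed
mean. Clustering is Lloyd's k-means (plain Euclidean distance on the
20-vector — CMA is already on [0, 1], z-scoring available), k-means++
seeding, best of 5 starts per k, empty clusters re-seeded from the
farthest point, convergence on stable assignments (max 200 iterations);
within-cluster SS is asserted non-increasing per iteration. k is chosen
over 2–6 by the Calinski–Harabasz criterion, with the Ray–Turi criterion
reported alongside, mirroring a selection that also weighs clinical
interpretability. Centroids are labelled from their first-4 versus
last-4 quarter means against a 0.8 threshold: high→high continuous
high, high→low decreasing, low→high increasing, low→low continuous
non-adherence; borderline centroids are flagged in a warning.

## CMA validation (ROC)

Each viral-load test is paired with the CMA over a 1/3/6/12-month
lookback ending the day before the test (tests with incomplete lookback
dropped and counted). Viral non-suppression (VNS) is viral load ≥ 400
copies/mL (100 and 1000 in sensitivity analyses). The AUC is the
Mann–Whitney probability that a non-suppressed test has lower CMA than a
suppressed one, ties half-weighted; 95% CIs come from a percentile
bootstrap resampling patients (clusters) with replacement, default
B = 500. A binormal probit AUC on rank-probit placement values is
provided as a secondary estimator. The empirical clustered-bootstrap
estimator was preferred as primary because it targets the same estimand
with no distributional assumptions and is fully specifiable.

## Risk-ratio models

The regression substrate is a person-period table: one row per complete
12-month CMA window (non-adherence outcome) or per viral-load test (VNS
outcome). Covariates are time-varying: mental-health category flags
(monotone once diagnosed; evaluated at period start for adherence rows
and at test date for VNS rows), age group (15–19, 20–24, 25–34
(reference), 35–44, 45–54, 55–64, 65+), and year since baseline rounded
up to the next integer, modelled categorically. Risk ratios come from a
modified Poisson fit — log-link Poisson working model for the binary
outcome with a patient-clustered sandwich variance and Wald 95% CIs. A
patient-level random-intercept variant (variational Bayes) exists behind
a flag, but the cluster-robust fit governs reported intervals because it
is the reproducible part of the original mixed-effects-plus-robust
specification. Adjustment sets: none; demographics (age, sex, year);
demographics + all six diagnosis categories; and additionally the
11-level CMA category (100, 90–99, …, 0–9) from the 12-month lookback
for mediation. Mediation is summarised as attenuation of the log-RR and
"fully mediated" when the CMA-adjusted CI includes 1 — adjustment
attenuation, not a causal decomposition.

Marginal ("standardised") predictions fix year-since-baseline at 2,
average model predictions over each stratum's observed covariate rows,
and use delta-method CIs. Trajectory-group membership is modelled by
multinomial logit (reference: continuous high) with categorical age,
sex, baseline diagnosis status and an age × sex interaction;
exponentiated coefficients are reported as relative risk ratios. With
sparse age × sex cells the Newton fit can fail to converge and rare-term
CIs can overflow; these are surfaced as warnings rather than hidden.

## Mental-health exposure

ICD-10 chapter-F codes group into organic (F00–F09), substance use
(F10–F19), serious (F20–F29, F31), depression (F32, F33, F34.1),
anxiety (F40–F48) and other (F30, F34.0/.8/.9, F50–F99) disorders.
Bare F34, its unlisted subcodes and F35–F39 fall to "other" so the six
categories partition the chapter; "any" is their union. Onset is the
first qualifying claim date (sensitivity definition: the date a second
claim on a distinct date arrives); outpatient and hospital claims count
equally. Exposure flags are monotone in time.

## Synthetic-data generator

The generator emulates the joint structure the analysis assumes, with
every magnitude taken from the published cohort the report layouts
follow:

* demographics — 58.9% female; age normal(40.1, 9.9) truncated at 15;
  baselines uniform over 2011–2020; log-normal follow-up with median
  3.5 years; coverage windows around baseline; database closure
  2020-06-30; labs only from 2016-01-01;
* mental health — a latent ever-diagnosed indicator at 38.1% prevalence
  (sex multipliers 1.13/0.84, mild age multipliers, centred so the
  population average stays on target), with within-diagnosed category
  prevalences (anxiety 68.7%, depression 53.0%, other 16.6%, serious
  6.0%, organic 2.4%, substance use 2.1%) so comorbidity is preserved;
  onset uniform from 2 years before baseline to follow-up end, followed
  by a renewal visit process emitting claims;
* behaviour classes — continuous high (flat 0.95), decreasing
  (0.95→0.25), increasing (0.30→0.90), continuous non-adherence (flat
  0.20) with quarterly Gaussian noise (sd 0.08); class probabilities
  from shares 23686/4152/2073/2343 of 32,254 with baseline-diagnosis
  multipliers (1.41/1.59/2.02) and age multipliers, pinned to the
  marginal shares by iterative proportional fitting;
* refills — 30-day supplies of a single fixed-dose-combination stream
  (J05AR; multi-stream mode available); the gap to the next refill is
  supply divided by current intended adherence with log-normal noise,
  so early refills, growing gaps and interruptions arise naturally;
* viral loads — Poisson testing at 1.5/year from the lab-availability
  date; P(VNS) follows a log-link model in the 12-month lookback
  adherence decile (gradient 1.00 → 15.89), age group (2.71 for 15–19
  down to 0.41 for 65+), male sex (1.47) and direct per-category
  diagnosis effects (substance use 1.03, i.e. essentially fully
  mediated by adherence), base probability 0.04, capped at 0.95.

Ground truth (behaviour class, intended trajectory, planted
coefficients) is exported with every cohort. Two structural simulators
bypass the claims layer for clean parameter recovery: a person-period
simulator planting an exact marginal risk ratio under log-normal
patient frailty, and a mediation simulator where substance use shifts
the adherence distribution that drives VNS.

What the generator does **not** emulate: mortality, regimen switching,
dose titration, informative viral-load testing (a dependent-testing mode
exists but is off by default), claim miscoding, and the real cohort's
exact joint covariate distribution. Passing recovery tests therefore
shows the estimators are correct under the assumed data-generating
process, not that real-data estimates would match published values. In
particular, the synthetic 12-month AUC (~0.71–0.73) sits below the
published real-data 0.82 because the planted decile gradient plus the
synthetic adherence distribution determine a different marginal
discrimination; the qualitative ordering (longer lookback ⇒ higher AUC)
is reproduced and tested.

## Problem sizes and numerics

Default analysis runs use cohorts of 2,000–3,000 patients; recovery
tests use n = 3,000 trajectories, n = 20,000 person-period patients for
point recovery and 100 replicates at n = 2,000 for CI coverage — sizes
at which the planted quantities are identifiable with comfortable
margins. All adherence arithmetic is double precision with no rounding
before report formatting; report percentages round half-away-from-zero
to one decimal. Window CMA values are clipped to [0, 1] against
accumulated float drift (≤ 1e-12). All randomness flows from explicit
seeds; identical seeds give byte-identical synthetic tables and report
bundles.
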