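# Methods

## The decision problem

Roughly 6% of UK primary-care patients carry a penicillin allergy label
(PAL), most of them incorrectly. A penicillin allergy assessment pathway
(PAAP) — testing initiated from primary care by skin-prick test, skin-prick
plus oral challenge, or direct oral challenge — removes incorrect labels,
restoring access to first-line penicillins. `paapcea` models whether the
up-front cost of testing is offset by lower downstream healthcare costs and
better health-related quality of life, comparing a PAAP strategy against
usual care over a 5-year horizon from a health-system perspective (GBP,
2022–23 prices).

## Model structure

Each arm passes through a decision tree with four chance nodes:

1. **receive test** (probability `p_test`; reference values 0.910 PAAP,
   0.012 usual care);
2. **test result** (`p_positive`; a *positive* result indicates the patient
   is allergic);
3. **label removal**, conditional on the result (`p_delabel_neg` = 0.973
   PAAP; removal after a positive test is a structural zero);
4. **treatment failure (TF)** during year 1 — re-prescription of an
   alternative antimicrobial within 28 days of an index prescription —
   conditional on the (result, label) context.

This yields eight payoff-bearing terminal branches per arm (the
positive-and-delabelled pair exists but has structural probability zero).
Each branch carries a first-year cost payoff and an annual QALY payoff.
Expected year-1 payoffs are probability-weighted sums over branches.

**Extrapolation (years 2–5).** Annual QALYs are held constant at the year-1
value (no post-year-1 HRQoL data exist). Annual costs are predicted from a
multiplicative regression on the two states fixed at 12 months: PAL status
and year-1 TF status,

    cost(year t) = baseline × no_label_mult^(1−label) × tf_mult^tf,

with defaults baseline £1,450/year, `no_label_mult` 0.92 and `tf_mult` 1.42
— the midpoints of the observed 6–11% saving for de-labelled and 39–46%
excess for treatment-failure participants; the baseline is calibrated so
the usual-care state mix reproduces the observed second-year mean annual
cost (≈£1,519). When estimated from data, the same model is fitted as a
Gamma GLM with log link on exposure-annualised year-2+ costs (zero costs
offset by half the smallest positive cost).

**Discounting.** Year 1 is undiscounted; year t ≥ 2 is weighted by
(1+d)^−(t−1) at d = 3.5%/year. This convention is fixed by the published
per-period QALY rows: 0.429 × Σ_{t=2..5} 1.035^−(t−1) = 0.429 × 3.673080
reproduces the printed discounted years-2–5 value.

**Year-1 exposure fraction.** The tree's expected year-1 payoffs at the
reference parameter values (≈£1,390 and 0.870 QALYs for PAAP) are roughly
double the published per-period year-1 values (£684.141, 0.429). The origin
of that factor is not derivable from the printed inputs, so the model
exposes `year1_exposure_fraction` (default 1.0) rather than hard-coding
either behaviour; 0.5 approximately reproduces the published per-period
scale and is used for the probabilistic reproduction checks. The constant
annual QALY carried into years 2+ is the *scaled* year-1 value, consistent
with the published rows.

**Markov relabelling scenario.** During years 2..horizon, de-labelled
patients can be relabelled with a constant annual probability (absorbing
two-state chain; a 6-month rate r converts as 1−(1−r)²). On relabelling, a
patient's annual cost reverts to the labelled regression prediction and
their annual QALY to the labelled counterpart of their branch (same test
result and TF status). An earlier candidate rule — reverting to the arm's
*untested* branch QALY — was rejected because the untested PAAP branch has
a higher mean QALY (0.902) than the de-labelled branch (0.880), which would
make relabelling beneficial and contradicts the monotone loss of
cost-effectiveness the scenario is meant to express. Threshold relabelling
rates (where incremental cost crosses zero, and where INMB crosses zero)
are found by bisection on [0, 1] to 1e−6; absence of a sign change is
reported as a result, not an error.

## Parameters and uncertainty

Every uncertain parameter is a `(family, mean, sd)` triple on the natural
scale: Beta for probabilities and utilities, Lognormal for costs, `fixed`
for structural constants. Method-of-moments conversion is exact:
Beta α = mν, β = (1−m)ν with ν = m(1−m)/s² − 1; Lognormal σ² = ln(1+s²/m²),
μ = ln m − σ²/2. The bundled reference file carries the published point
estimates and SD column verbatim; these SDs are used directly as PSA
uncertainty (they are far larger than binomial standard errors at n≈400,
and only at this scale does the probability of cost-effectiveness land near
50%). When parameters are re-estimated from individual-level data, the
engine records the sample SD of the branch indicator by default and the
binomial SE under the `se` option.

Branches with no observed members are filled by substitution with fixed
(sd 0) values: QALYs from the corresponding branch of the other arm, costs
from the same arm's untested branch matched on TF status, with fallbacks
through the other arm and the untested no-TF branch so that extreme designs
(e.g. the As-Treated reassignment, which empties the PAAP no-test branch)
remain estimable. Substituted entries are flagged in a provenance map and
excluded from PSA.

The PSA draws every non-fixed parameter independently (no correlation
structure is published); all draws are propagated through the full 5-year
model vectorised, so deterministic and probabilistic evaluation share one
code path. Probability of cost-effectiveness counts INMB strictly > 0.
The post-year-1 regression coefficients are held at their point estimates
during PSA.

## Synthetic trial generator

`synthetic_trial` emulates the structure the analysis assumes: two arms
(401/410 by default), branch membership drawn from the tree's conditional
probabilities at the reference truth values, first-year costs composed of
six service components (test, primary-care consultations, medications,
admissions, outpatient visits, emergency attendances) drawn from Gamma
distributions scaled so each branch's expected total equals its reference
payoff, annual utilities from moment-matched Beta distributions, year-2+
costs from the multiplicative label/TF process (Gamma noise, CV 2), and
administrative censoring that shortens one year's exposure window with
proportional cost reduction and drops later years. Costs are annualised
(×365/exposure days) before estimation, mirroring the published censoring
adjustment. Covariates (age ≈ N(54, 16²) clipped to 18–95, 72% female, QOF
conditions ~ Poisson(1.8), baseline antibiotic courses ~ Poisson(1.9))
are independent of outcomes except through an optional utility bonus for
de-labelled patients aged 65+ (`age_qaly_interaction`), used to verify
subgroup sign recovery.

What the generator does *not* emulate: within-year cost trajectories,
individual prescription or infection episodes, EQ-5D item responses,
informative censoring, correlated covariate-outcome structure, or any
pandemic-era disruption. Passing recovery tests therefore demonstrates
internal consistency of the estimation-to-decision pipeline, not fidelity
to any real cohort.

## Value of information

With two strategies the net-benefit framework reduces to the incremental
net benefit INB(λ) = λΔQ − ΔC, and every information measure is
E[max(E[INB|X],0)] − max(E[INB],0) for the appropriate conditioning X.
EVPPI uses cubic-basis regression of per-draw INB on a single parameter;
EVSI simulates, per PSA draw, a follow-on trial's summary statistics
(binomial per-arm TF counts; for full endpoints also noisy mean cost and
utility differences) and regresses INB on them (quadratic basis, features
z-scored before expansion — unscaled polynomial features of GBP-magnitude
columns make the OLS design numerically rank-deficient). Estimates are
clipped to [0, EVPI].

Trial cost and duration are linear in n, calibrated through the published
(769, £1.76M, 30 months) and (1267, £2.37M, 46 months) anchor pairs,
giving ≈£1,225/participant over £818k fixed and ≈0.0321 months/participant
over 5.3 months. Population scaling assumes uniform annual cohorts of the
10-year eligible population (79,877) discounted at 3.5% from year 1. ENBS
is evaluated on an n-grid (default 50..2000 by 50) without assuming
concavity; if negative everywhere the recommended n is 0.

A structural finding worth knowing: with the reference uncertainty the
QALY payoff parameters dominate INB variance, so the arm-level TF contrast
carries almost no decision-relevant information and clinical-endpoints-only
EVSI evaluates to ≈0, while full-endpoint EVSI is large and approaches its
informed-set EVPPI limit. The published per-patient EVSI for a
clinical-only trial is small but positive; reproducing it would require the
unpublished EVSI machinery, so it serves only as a calibration anchor for
the trial cost/duration models here.

## Numerical choices and degenerate inputs

- Path probabilities conserve mass to 1e−12 for any feasible parameter set.
- Boundary probabilities (0 or 1) and zero-SD payoffs become `fixed` and
  are excluded from PSA; single-member branches are flagged degenerate.
- Beta estimation clamps an estimated SD to just below the feasibility
  bound √(m(1−m)).
- Dominance classes are strict: *dominant* requires ΔC<0 and ΔQ>0;
  south-west ratios are reported positive as savings per QALY lost; ΔQ=0
  yields an `undefined` flag, never an exception. PSA summaries report
  mean ΔC and ΔQ, never a mean of ratios.
- The whole pipeline is seeded: same config + seed gives bit-identical
  output files.

## Problem sizes used in the test suite

Recovery checks generate 100,000 participants per arm for branch
probabilities and payoffs and 25,000 per arm for the cost-regression
multipliers (recovered within 5% relative error); probabilistic checks use
4,000–10,000 PSA draws. These sizes put Monte-Carlo noise comfortably
inside the 3-standard-error and ±5% acceptance bands while keeping the
default suite under a minute of compute.

## Known limitations

- Five-year horizon with no mortality, no half-cycle correction, and no
  re-drawing of TF status after year 1.
- Independent PSA draws; the optional individual-level route to correlated
  uncertainty is re-estimation from a bootstrap of the synthetic cohort,
  not a parameter correlation matrix.
- The year-1 payoff scale ambiguity described above means absolute
  incremental costs/QALYs depend on `year1_exposure_fraction`; incremental
  *directions* and probability statements are stable across the plausible
  settings.
- Subgroup analyses re-estimate all parameters within each stratum and
  inherit small-sample noise; strata with an empty arm are reported with a
  flag rather than analysed.
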