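# paapcea

Cost-effectiveness and value-of-information analysis of **penicillin
allergy assessment pathways** (PAAP) — primary-care-initiated allergy
testing and de-labelling — against usual care.

Around 6% of UK primary-care patients carry a penicillin allergy label,
most of them wrong. A wrong label pushes prescribing toward
broader-spectrum, costlier, often less effective antibiotics. Testing
patients and removing incorrect labels costs money up front; this package
models whether that investment pays off in healthcare costs and
quality-adjusted life years (QALYs) over five years, for health economists
and trialists designing or appraising de-labelling programmes.

## The model

A per-arm decision tree walks each patient through: receive an allergy
test or not → test result → penicillin-allergy-label (PAL) removal →
treatment failure (TF) in year 1. Its eight payoff-bearing terminal
branches carry first-year cost and annual QALY payoffs. Years 2–5 hold
QALYs constant at the year-1 value and predict annual costs from a
multiplicative regression on 12-month label and TF status
(cost = b·m_label^(1−label)·m_TF^tf); years t ≥ 2 are discounted by
(1+0.035)^−(t−1).

Strategies are compared by incremental cost ΔC, incremental QALYs ΔQ, the
ICER ΔC/ΔQ with the usual dominance conventions, and incremental net
monetary benefit INMB(λ) = λ·ΔQ − ΔC at thresholds of £20,000 and £30,000
per QALY. Parameter uncertainty (Beta for probabilities and utilities,
Lognormal for costs, both moment-matched) is propagated by Monte-Carlo
probabilistic sensitivity analysis (PSA), summarised as cost-effectiveness
acceptability curves and cost-effectiveness-plane clouds. On top of the
PSA sit the value-of-information estimators — EVPI, per-parameter EVPPI,
EVSI for a follow-on two-arm trial, and expected net benefit of sampling
over candidate sample sizes — plus scenario machinery: Markov relabelling
of de-labelled patients in years 2–5, As-Treated reassignment, alternative
test unit costs, and covariate subgroups.

A bundled parameter file carries the published estimates from the ALABAMA
randomised trial of PAAP (401 vs 410 participants); alternatively, every
parameter can be re-estimated from individual-level data, and a synthetic
trial generator produces such data with the assumed structure so the whole
pipeline is testable end to end.

## Worked example

```python
import paapcea as pc

params = pc.load_reference_params()
reg = pc.default_cost_regression()
econ = pc.EconConfig(year1_exposure_fraction=0.5, psa_draws=10_000, seed=1)

det = pc.deterministic_cea(params, reg, econ)
print(f"deterministic: dC = {det.delta_cost:+.1f} GBP, "
      f"dQ = {det.delta_qaly:+.4f} QALYs, {det.icer.dominance_class}")

draws, psa = pc.run_psa(params, reg, econ)
print(f"PSA means:     dC = {psa.mean_delta_cost:+.1f} GBP, "
      f"dQ = {psa.mean_delta_qaly:+.4f} QALYs")
print(f"INMB:          {psa.inmb[20000.0]:.0f} GBP @ 20k, "
      f"{psa.inmb[30000.0]:.0f} GBP @ 30k")
print(f"P(cost-effective): {psa.p_cost_effective[20000.0]:.1%} @ 20k, "
      f"{psa.p_cost_effective[30000.0]:.1%} @ 30k")
print(f"P(cost saving):    {psa.p_cost_saving:.1%}")

from paapcea import voi_engine as voi
print(f"EVPI per patient:  {voi.evpi(draws, 20000):.0f} GBP")
design = voi.default_trial_design(endpoints="full")
print(f"EVSI (full data, n=1267): "
      f"{voi.evsi(draws, design, 20000, seed=1):.0f} GBP/patient")
print(f"follow-on trial cost at n=1267: {voi.trial_cost(design)/1e6:.2f}M GBP,"
      f" duration {voi.trial_duration(design):.0f} months")
```

prints:

```
deterministic: dC = -371.3 GBP, dQ = +0.0711 QALYs, dominant
PSA means:     dC = -374.6 GBP, dQ = +0.0694 QALYs
INMB:          1762 GBP @ 20k, 2456 GBP @ 30k
P(cost-effective): 53.1% @ 20k, 52.3% @ 30k
P(cost saving):    70.0%
EVPI per patient:  2548 GBP
EVSI (full data, n=1267): 2521 GBP/patient
follow-on trial cost at n=1267: 2.37M GBP, duration 46 months
```

Read: at these inputs PAAP *dominates* usual care — it saves about £370
per patient over five years and gains about 0.07 QALYs — but the decision
is genuinely uncertain: the probability that it is the cost-effective
choice at £20,000/QALY is only ~53%. Eliminating all parameter uncertainty
would be worth ~£2,500 per future patient (EVPI), and a follow-on trial of
1,267 participants collecting cost and quality-of-life endpoints would
capture nearly all of that value at a cost of £2.37M.

## Command line

```sh
paapcea generate --out cohort/ --seed 7          # synthetic trial data
paapcea estimate --data cohort/ --out params.yaml
paapcea run --mode from_table --out run/ --voi   # full pipeline
paapcea run --mode from_synthetic --out run2/ --relabel-rate 0.066
paapcea report --run-dir run/
```

`run` writes a parameter snapshot, deterministic and PSA summaries, CEAC
and CE-plane tables, scenario sensitivity analyses, relabelling-rate
thresholds, optional subgroup and VOI outputs, and a markdown report —
all seeded and bit-reproducible.

## Layout

- `src/paapcea/parameter_engine.py` — distribution specs, moment matching,
  estimation from individual data, post-year-1 cost regression
- `src/paapcea/decision_model.py` — tree enumeration, extrapolation,
  Markov relabelling, thresholds
- `src/paapcea/cea_engine.py` — ICER/INMB, PSA, CEAC, subgroups
- `src/paapcea/voi_engine.py` — EVPI, EVPPI, EVSI, ENBS, trial economics
- `src/paapcea/synthetic_trial.py` — cohort generator, censoring,
  As-Treated, summaries
- `src/paapcea/pipeline.py`, `cli.py` — configuration-driven runs
- `docs/methods.md` — modelling assumptions, design choices, limitations
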