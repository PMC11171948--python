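# ppdcea

Decision-analytic cost-effectiveness modelling of postpartum-depression
(PPD) prevention and treatment strategies, built for health-economics
researchers and health-policy analysts who want a fully scriptable,
testable alternative to spreadsheet or TreeAge-style decision-tree models.

The package compares three strategies for a simulated cohort of 10,000
pregnant women over a two-year postnatal horizon:

* **routine care** — no active screening; women with PPD receive
  psychotherapy only if they seek it themselves;
* **early postnatal screening** — universal EPDS screening within eight
  weeks of delivery (score ≥ 12 flags high risk), SCID confirmation for
  screen-positive women who attend referral, then guideline treatment;
* **prenatal psychological intervention** — an antenatal EPDS screen
  identifies high-risk pregnant women, who receive six sessions of group
  cognitive-behavioural therapy that halves their PPD risk; the postnatal
  screening pathway then applies to everyone.

## Model

The structural model is a single-pass decision tree.  Costs (USD) accrue
on branches as events happen — screening, SCID assessment, psychotherapy,
medication, PPD care — and utilities attach to terminal health states
(no PPD, recovered, unrecovered, suicidal ideation, death).  Effectiveness
is measured in quality-adjusted life years on a normalized horizon
(1 QALY-unit = perfect health for the whole horizon), and strategies are
compared by the incremental cost-effectiveness ratio

    ICER = (C_a − C_ref) / (E_a − E_ref)   [USD per QALY]

against a willingness-to-pay threshold of USD 11,300 per QALY (China's GDP
per capita), with the WHO GDP-multiple classification.  Uncertainty is
handled three ways: one-way ±20% deterministic sensitivity analysis
(tornado), probabilistic sensitivity analysis with 10,000 joint draws from
beta (probabilities, utilities) and gamma (costs) distributions fitted by
method of moments so every mean equals its point estimate, and scenario
analyses (referral attendance 20–100%, treatment costs +50%/+100%).

Evaluation routes: exact expected-value rollback, brute-force path
enumeration (the internal oracle), and individual-level microsimulation.
Cohort comparisons share one scrambled-Sobol uniform matrix keyed by event
label, so the same woman experiences the same events in every arm (common
random numbers) and incremental results carry little Monte-Carlo noise.

Two treatment cure probabilities (psychotherapy 0.87, pharmaceutical/mixed
0.92 over the horizon) are **calibrated, not literature-sourced**; every
report discloses them.  See `docs/methods.md`.

## Worked example

```sh
python examples/01_base_case.py
```

prints (seed 2024):

```
Cost-effectiveness table (costs USD/woman, effects QALY on a
normalized horizon where 1 = two healthy years; ICER = USD per QALY):
                           strategy   cost  effect  incremental_cost  incremental_effect    icer
                       routine_care  76.78    0.95               NaN                 NaN     NaN
          early_postnatal_screening 100.61    0.96             23.84                0.00 7961.78
prenatal_psychological_intervention 121.01    0.97             44.23                0.02 2237.80
```

Routine care is cheapest but leaves ~1,300 of 10,000 women with
unresolved PPD; screening buys extra QALYs at ≈ USD 7,960 per QALY and
the prenatal intervention at ≈ USD 2,240 per QALY — both well under the
USD 11,300 willingness-to-pay threshold, with the prenatal intervention
the preferred strategy.  (ICERs are computed at full precision; the
displayed increments are rounded to two decimals.)

Other examples: `02_tornado_dsa.py` (one-way sensitivity),
`03_psa_ceac.py` (PSA and acceptability curves), `04_scenarios.py`
(referral and cost scenarios), `05_engine_validation.py` (engine
self-checks on synthetic trees).

A thin CLI wraps the same library calls:

```sh
ppdcea run-all --seed 5 --out results/     # base case + DSA + PSA + scenarios
ppdcea plot --results results/             # tornado / CEAC / scatter figures
```

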