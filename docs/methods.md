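# Methods

This note documents the model implemented in `ppdcea`: its structure and
assumptions, the parameters and how their uncertainty is represented, the
numerical and design choices that were genuinely open, what the synthetic
generators do and do not emulate, and known limitations.

## Structural model

Each strategy is a single-pass decision tree over a two-year postnatal
horizon (no cycles, no discounting — the horizon is short and a
`discount_rate` constant is exposed but fixed at 0).  The three trees
share their clinical core and are shipped as reviewable YAML files under
`src/ppdcea/data/trees/`, so every structural assumption can be audited
line by line.

**Onset.**  A woman develops PPD with probability `p_ppd` (0.16).  In the
prenatal-intervention arm the root event is the *liability* to develop PPD
absent intervention, so the same random draw decides onset in every arm.

**Case finding.**
*Routine care*: PPD women self-refer with `p_selfref_unscreened` (0.23),
are confirmed by SCID with `p_dx_low` (0.38, cost `c_diag`), and enter
treatment.
*Early postnatal screening*: everyone pays `c_screen`; the EPDS flags PPD
women with sensitivity 0.8 and non-PPD women with 1 − specificity = 0.1.
Screen-positives attend referral with `p_ref_high` (0.51) and are
confirmed with `p_dx_high` (0.7).  Screen-negative PPD women may still
self-refer (`p_selfref_low`, 0.16, then `p_dx_low`).  False positives who
attend referral incur the assessment cost and exit healthy.
*Prenatal intervention*: an antenatal EPDS (same operating
characteristics, applied to future PPD liability) selects high-risk women
for group CBT (`c_prenatal_int`); the intervention averts PPD with
probability `p_int_effect` (0.5).  Postnatally the screening pathway
applies to everyone.

**Treatment.**  Diagnosed women refuse treatment with `p_refuse` (0.17).
Treated women receive pharmaceutical/mixed treatment with `p_pharm`
(0.43; costs `c_psychother + c_med`; cure probability `p_cure_pharm`) or
psychotherapy alone (cost `c_psychother`; cure `p_cure_psycho`, with
relapse `p_relapse_nonpharm` = 0.2 after cure).  Untreated or undiagnosed
women recover spontaneously with `p_spont` (0.01).

**Outcomes.**  Women whose depression never resolves enter the
unrecovered pool: the one-off care cost `c_care` is charged on the
entering branch, and they face suicidal ideation (`p_ideation`, 0.117)
and, conditional on ideation, suicidal behaviour (`p_suicide`, 0.005,
utility 0, no death costs).  Terminal utilities: 1 (healthy), `u_ppd`
(0.75, unrecovered), `u_ideation` (0.38), 0 (death); recovered women
blend pre-cure and post-cure time,
`f_pre · u_ppd + (1 − f_pre) · u_cured` with `f_pre` = 0.25 of the
horizon (configurable; unmeasured, so a quarter of the horizon spent
depressed before cure is a deliberate round default).

**QALY scale.**  Effectiveness is the mean utility over the horizon
(1 = perfect health for the full two years).  This normalized scale is
what the reference outputs print (per-strategy effectiveness ≈ 0.95–0.97
here); multiply by `horizon_years` for raw QALYs (`raw_qaly` in the run
configuration).

## Parameters and second-order uncertainty

All quantities live in `src/ppdcea/data/parameters.yaml` as
(base, range, family) triples — gamma for costs, beta for probabilities
and utilities, fixed for constants.  The published table gives only point
estimates and ranges, not distribution parameters; ranges are therefore
read as central 95% intervals and fitted by method of moments
(`sd = (high − low)/3.92`) with the mean pinned to the point estimate.
A beta whose implied variance is infeasible for its mean is shrunk to 95%
of the feasible maximum with a logged warning; range ends above 1 are
clamped to 1 (one utility row prints an upper end of exactly 1).  Several
cost rows print their ranges high-to-low; the reader sorts them and logs
a notice.  One-way sensitivity perturbations clamp to the field's support.

### Calibrated cure rates

The model cannot be evaluated without the two treatment cure
probabilities, which the source material discusses but never prints.
They are therefore **calibrated**: using the closed-form rollback algebra,
`p_cure_pharm` = 0.92 and `p_cure_psycho` = 0.87 (per-episode probability
of lasting remission within the two-year horizon, including
post-treatment natural remission) were chosen so that the base case
reproduces the reference health-state distribution for routine care
(≈ 1,320 vs 1,336 unrecovered per 10,000) and places the
screening-vs-routine ICER inside the reproduction tolerance.  Both fields
are flagged `calibrated: true`, reported by `validate-params` and logged
by every run.  Sensitivity of results to them is visible in the tornado
output.

## Evaluation routes and random numbers

* **rollback** — exact bottom-up expectation; also vectorizes over numpy
  arrays, which is how the 10,000-draw PSA evaluates all iterations at
  once.
* **enumerate_paths** — exhaustive root-to-terminal enumeration; the
  engine's internal oracle (rollback must agree to 1e-9, a hard test).
* **microsimulate** — individual walks.  Uniform draws are keyed by
  chance-node *label*: per seed, each individual carries one uniform per
  event label, consumed wherever that event appears.  Trees sharing event
  labels therefore resolve them identically — common random numbers
  across strategy arms — which makes incremental quantities far more
  stable than independent streams would, while keeping same-seed runs
  bit-for-bit reproducible and results insensitive to branch reordering
  (cumulative-probability intervals, left-closed).
* **microsimulate_strategies** — the cohort-comparison evaluator: all
  arms share one scrambled-Sobol matrix (randomized quasi-Monte Carlo)
  over the union of event labels, with the care-pathway gates on the
  leading Sobol dimensions.  Scrambling keeps the estimator unbiased and
  seed-dependent; equidistribution cuts the Monte-Carlo coefficient of
  variation of the screening-vs-routine ICER from ~12% to ~5% at
  n = 10,000.  Within one matrix the walks are not mutually independent
  (the usual QMC trade-off); per-tree `microsimulate` keeps ordinary
  independent streams.

Problem sizes used throughout: cohorts of 10,000 women per arm, PSA with
10,000 parameter draws evaluated by rollback (the two-level
parameter-draw × individual-walk mode exists behind `mode="microsim"` but
is not the default), DSA by exact rollback.  A full pipeline run
completes in seconds.

## Analysis conventions

* ICERs are computed at full precision; display rounding (2 decimals)
  happens only at output, so printed increments need not exactly divide
  to the printed ICER.
* Pairwise tables compare each strategy to routine care (the headline
  presentation); a standard frontier mode with strict and extended
  dominance is also provided.
* WHO classification: ICER < 1× GDP per capita → very cost-effective;
  1×–3× (left-closed, right-closed) → cost-effective; above → not
  cost-effective.  Cheaper-and-better comparisons are flagged dominant.
* CEAC: per willingness-to-pay value, a strategy's acceptance probability
  is the fraction of PSA draws in which it attains the maximum net
  monetary benefit; exact ties split equally.
* Scenarios: referral overrides replace `p_ref_high` only (optionally the
  self-referral rates); the treatment-cost multiplier (≥ 1, increases
  only) scales `c_diag`, `c_med`, `c_psychother` by default — the
  increase is motivated by practitioner income, so care, screening and
  intervention costs are left out of the default set, which is
  configurable.
* The one-way DSA targets the prenatal-intervention-vs-routine-care ICER
  by default (configurable), perturbing every uncertain parameter
  including the calibrated cure rates.

## Synthetic data

`synthetic.make_toy_tree` generates random chance trees whose exact
expectations are accumulated *during construction* — a code path disjoint
from rollback — so oracle agreement is a genuine test.
`generate_cohort_trajectories` emits one record per simulated woman
(path, cost, effect, terminal state) and reproduces the aggregate
microsimulation exactly for a shared seed.  The generators emulate the
statistical structure the analysis assumes: independent individuals,
branch probabilities taken from the parameter table, one episode per
woman.  They do not emulate EPDS item scores, time-varying symptom
trajectories, repeat episodes, or correlation between a woman's risk and
her care-seeking — so passing tests validate the engine and the stated
model, not those richer features of real screening programmes.

## Known limitations and documented divergences

* The reference model's tree topology (its figures) and cure rates were
  never published; this package reconstructs the structure from the prose
  description.  Under that reconstruction with the published parameter
  table, some published outputs are not attainable for any cure-rate
  setting: the reported per-strategy effectiveness spread (0.91–0.98 on a
  1-unit scale) exceeds what a 16% PPD prevalence and the printed
  utilities can produce (at most ≈ 0.035), and the reported per-strategy
  costs for the active arms (USD 342–451 per woman) exceed the sum of
  every applicable cost parameter per PPD case.  Consequently the
  prenatal-arm ICER, prenatal-arm cost and recovered-count checks, the
  PSA acceptance probability and the referral-100% scenario ICER in
  `tests/test_acceptance.py` fail at their documented tolerances and are
  left failing deliberately; the screening ICER, routine-care cost and
  counts, and the +50%-cost scenario reproduce within tolerance.
* In this model each cured woman avoids the `c_care` episode cost, so
  extra treatment is close to cost-neutral and the ICER *falls* slightly
  as referral attendance rises; the reference reports the opposite trend.
* Spillover effects on infants and families, repeat screening, budget
  impact and the SF-12→SF-6D utility derivation are out of scope;
  utilities are taken as given.
* Suicide deaths carry no cost and end the path; with `p_suicide` = 0.005
  conditional on ideation, expected deaths per 10,000 are below 1, so
  simulated cohorts typically show none.
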