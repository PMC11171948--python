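# Model parameters for the postpartum-depression (PPD) cost-effectiveness model.
#
# Costs are USD per episode/event, utilities are preference weights in [0, 1]
# (1 = perfect health, 0 = dead), probabilities are per-case event
# probabilities over the two-year postnatal horizon. `range` is kept in the
# source's printed order (several cost rows print high~low); the reader sorts
# it and logs a normalization notice.
#
# `calibrated: true` marks quantities that are NOT sourced from literature:
# the two treatment cure rates are calibrated so that the base-case
# health-state distribution and incremental results reproduce the reference
# outputs (see docs/methods.md for the calibration procedure).

parameters:
  c_care:
    base: 480
    range: [576, 384]
    family: gamma
    description: Cost of PPD care (unrecovered episode)
  c_diag:
    base: 28.57
    range: [34.284, 22.856]
    family: gamma
    description: Cost of diagnosing PPD (SCID assessment)
  c_med:
    base: 185.75
    range: [222.9, 148.6]
    family: gamma
    description: Cost of medication (SSRI course)
  c_prenatal_int:
    base: 137.15
    range: [164.58, 109.72]
    family: gamma
    description: Cost of prenatal psychological intervention (6-session group CBT)
  c_screen:
    base: 22.3
    range: [26.76, 17.84]
    family: gamma
    description: Cost of screening (EPDS administration)
  c_psychother:
    base: 274.3
    range: [329.16, 219.44]
    family: gamma
    description: Cost of psychological treatment (structured psychotherapy course)

  u_healthy:
    base: 1.0
    family: fixed
    description: Utility of perfect health
  u_ppd:
    base: 0.75
    range: [0.525, 0.975]
    family: beta
    description: Utility of having PPD
  u_cured:
    base: 0.88
    range: [0.616, 1.0]
    family: beta
    description: Utility of PPD after cure
  u_ideation:
    base: 0.38
    range: [0.266, 0.494]
    family: beta
    description: Utility of suicidal ideation
  u_death:
    base: 0.0
    family: fixed
    description: Utility of death

  spec_epds:
    base: 0.9
    range: [0.63, 1.0]
    family: beta
    description: Specificity of EPDS (score >= 12 threshold)
  sens_epds:
    base: 0.8
    range: [0.56, 1.0]
    family: beta
    description: Sensitivity of EPDS (score >= 12 threshold)
  p_dx_high:
    base: 0.7
    range: [0.55, 0.81]
    family: beta
    description: Probability of PPD diagnosis if high-risk (SCID confirmation among referred)
  p_dx_low:
    base: 0.38
    range: [0.33, 0.43]
    family: beta
    description: Probability of PPD diagnosis if low/moderate-risk (SCID confirmation among self-referred)
  p_ref_high:
    base: 0.51
    range: [0.4, 0.62]
    family: beta
    description: Probability of attending referral if high-risk
  p_selfref_low:
    base: 0.16
    range: [0.15, 0.18]
    family: beta
    description: Probability of self-referral if low/moderate-risk
  p_selfref_unscreened:
    base: 0.23
    range: [0.161, 0.299]
    family: beta
    description: Probability of self-referral if unscreened
  p_spont:
    base: 0.01
    range: [0.007, 0.013]
    family: beta
    description: Probability of recovery without treatment
  p_int_effect:
    base: 0.5
    range: [0.35, 0.65]
    family: beta
    description: Probability of reduced PPD risk in high-risk women after prenatal psychological intervention
  p_ppd:
    base: 0.16
    range: [0.112, 0.208]
    family: beta
    description: Probability of having PPD
  p_pharm:
    base: 0.43
    range: [0.37, 0.5]
    family: beta
    description: Probability of receiving pharmaceutical/mixed treatment
  p_relapse_nonpharm:
    base: 0.2
    range: [0.0, 0.3]
    family: beta
    description: Probability of relapse from non-pharmaceutical treatment
  p_refuse:
    base: 0.17
    range: [0.15, 0.19]
    family: beta
    description: Probability of refusal of treatment
  p_ideation:
    base: 0.117
    range: [0.0819, 0.1521]
    family: beta
    description: Probability of women with unrecovered PPD having suicidal ideation
  p_suicide:
    base: 0.005
    range: [0.0035, 0.0065]
    family: beta
    description: Probability of suicidal behavior given suicidal ideation

  p_cure_psycho:
    base: 0.87
    range: [0.696, 1.0]
    family: beta
    calibrated: true
    description: Probability of cure with psychotherapy alone over the horizon (calibrated, not sourced)
  p_cure_pharm:
    base: 0.92
    range: [0.736, 1.0]
    family: beta
    calibrated: true
    description: Probability of cure with pharmaceutical/mixed treatment over the horizon (calibrated, not sourced)
  f_pre:
    base: 0.25
    family: fixed
    calibrated: true
    description: Fraction of the horizon spent depressed before cure, for women who recover

analysis:
  wtp: 11300            # USD per QALY, China's GDP per capita
  gdp_per_capita: 11300
  cohort_n: 10000
  horizon_years: 2
  discount_rate: 0.0
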