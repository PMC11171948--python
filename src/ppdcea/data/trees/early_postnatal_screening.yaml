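kind: chance
label: ppd_onset
branches:
- label: ppd
  prob: p_ppd
  cost: c_screen
  child:
    kind: chance
    label: postnatal_screen
    branches:
    - label: screen_positive
      prob: sens_epds
      cost: '0'
      child:
        kind: chance
        label: referral
        branches:
        - label: attends_referral
          prob: p_ref_high
          cost: c_diag
          child:
            kind: chance
            label: diagnosis
            branches:
            - label: confirmed
              prob: p_dx_high
              cost: '0'
              child: &id003
                kind: chance
                label: treatment_refusal
                branches:
                - label: refuses_treatment
                  prob: p_refuse
                  cost: '0'
                  child: &id002
                    kind: chance
                    label: spontaneous_recovery
                    branches:
                    - label: spontaneous_recovery
                      prob: p_spont
                      cost: '0'
                      child:
                        kind: terminal
                        label: ppd_recovered
                        payoff:
                          cost: '0'
                          effect: f_pre * u_ppd + (1 - f_pre) * u_cured
                          tag: ppd_recovered
                    - label: remains_depressed
                      prob: 1 - p_spont
                      cost: c_care
                      child: &id001
                        kind: chance
                        label: ideation
                        branches:
                        - label: ideation
                          prob: p_ideation
                          cost: '0'
                          child:
                            kind: chance
                            label: suicide
                            branches:
                            - label: suicidal_behavior
                              prob: p_suicide
                              cost: '0'
                              child:
                                kind: terminal
                                label: suicide_death
                                payoff:
                                  cost: '0'
                                  effect: u_death
                                  tag: suicide_death
                            - label: no_suicidal_behavior
                              prob: 1 - p_suicide
                              cost: '0'
                              child:
                                kind: terminal
                                label: suicidal_ideation
                                payoff:
                                  cost: '0'
                                  effect: u_ideation
                                  tag: suicidal_ideation
                        - label: no_ideation
                          prob: 1 - p_ideation
                          cost: '0'
                          child:
                            kind: terminal
                            label: ppd_unrecovered
                            payoff:
                              cost: '0'
                              effect: u_ppd
                              tag: ppd_unrecovered
                - label: accepts_treatment
                  prob: 1 - p_refuse
                  cost: '0'
                  child:
                    kind: chance
                    label: treatment_modality
                    branches:
                    - label: pharmaceutical_mixed
                      prob: p_pharm
                      cost: c_psychother + c_med
                      child:
                        kind: chance
                        label: pharm_cure
                        branches:
                        - label: cured
                          prob: p_cure_pharm
                          cost: '0'
                          child:
                            kind: terminal
                            label: ppd_recovered
                            payoff:
                              cost: '0'
                              effect: f_pre * u_ppd + (1 - f_pre) * u_cured
                              tag: ppd_recovered
                        - label: not_cured
                          prob: 1 - p_cure_pharm
                          cost: c_care
                          child: *id001
                    - label: psychotherapy_only
                      prob: 1 - p_pharm
                      cost: c_psychother
                      child:
                        kind: chance
                        label: psycho_cure
                        branches:
                        - label: cured
                          prob: p_cure_psycho
                          cost: '0'
                          child:
                            kind: chance
                            label: relapse
                            branches:
                            - label: relapse
                              prob: p_relapse_nonpharm
                              cost: c_care
                              child: *id001
                            - label: sustained_recovery
                              prob: 1 - p_relapse_nonpharm
                              cost: '0'
                              child:
                                kind: terminal
                                label: ppd_recovered
                                payoff:
                                  cost: '0'
                                  effect: f_pre * u_ppd + (1 - f_pre) * u_cured
                                  tag: ppd_recovered
                        - label: not_cured
                          prob: 1 - p_cure_psycho
                          cost: c_care
                          child: *id001
            - label: not_confirmed
              prob: 1 - p_dx_high
              cost: '0'
              child: *id002
        - label: declines_referral
          prob: 1 - p_ref_high
          cost: '0'
          child: *id002
    - label: screen_negative
      prob: 1 - sens_epds
      cost: '0'
      child:
        kind: chance
        label: self_referral
        branches:
        - label: seeks_care
          prob: p_selfref_low
          cost: c_diag
          child:
            kind: chance
            label: diagnosis
            branches:
            - label: confirmed
              prob: p_dx_low
              cost: '0'
              child: *id003
            - label: not_confirmed
              prob: 1 - p_dx_low
              cost: '0'
              child: *id002
        - label: no_care_seeking
          prob: 1 - p_selfref_low
          cost: '0'
          child: *id002
- label: no_ppd
  prob: 1 - p_ppd
  cost: c_screen
  child:
    kind: chance
    label: postnatal_screen
    branches:
    - label: screen_positive
      prob: 1 - spec_epds
      cost: '0'
      child:
        kind: chance
        label: referral
        branches:
        - label: attends_referral
          prob: p_ref_high
          cost: c_diag
          child:
            kind: terminal
            label: no_ppd
            payoff:
              cost: '0'
              effect: u_healthy
              tag: no_ppd
        - label: declines_referral
          prob: 1 - p_ref_high
          cost: '0'
          child:
            kind: terminal
            label: no_ppd
            payoff:
              cost: '0'
              effect: u_healthy
              tag: no_ppd
    - label: screen_negative
      prob: spec_epds
      cost: '0'
      child:
        kind: terminal
        label: no_ppd
        payoff:
          cost: '0'
          effect: u_healthy
          tag: no_ppd
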