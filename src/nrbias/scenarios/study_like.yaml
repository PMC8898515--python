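# Study-scale synthetic scenario: a gender-blocked 3x2x2 factorial mailed
# survey of 480 men and 480 women with the motivating trial's sampling-frame
# prevalences, an overall response rate near 43%, a higher return under the
# $40 incentive and the claims-list framing, and nonignorable response for
# both self-reports (combat survivors respond more, military-sexual-assault
# survivors less). Coefficients are scenario parameters, not estimates of
# the trial's actual response process.
frame:
  n_per_block: 480
  covariate_prevalence:
    men:
      age_lt30: 0.304
      nonwhite: 0.419
      combat_admin: 0.671
      mst_admin: 0.021
      smi: 0.052
      charlson_gt0: 0.117
      any_benefits: 0.819
      ptsd_benefits: 0.563
    women:
      age_lt30: 0.323
      nonwhite: 0.594
      combat_admin: 0.413
      mst_admin: 0.456
      smi: 0.082
      charlson_gt0: 0.100
      any_benefits: 0.773
      ptsd_benefits: 0.452
outcomes:
  self_combat:
    intercept: 0.2
    combat_admin: 2.2
  self_msa:
    intercept: -2.2
    mst_admin: 2.8
    nonwhite: 0.2
response:
  alpha:
    intercept: -1.05
    incentive_usd40: 0.45
    source_claims_list: 0.25
    age_lt30: -0.35
    any_benefits: 0.45
    smi: 0.30
  gamma:
    self_combat: 0.6
    self_msa: -0.9
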