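# Study-scale synthetic cohort: 1977 responses = 569 legitimate
# + 327 ineligible + 1081 fraudulent (planted indicator marginals below).
seed: 0
n_legit: 569
n_fraud: 1081
stage1_counts:
  non_us_resident: 28
  stage_0: 28
  no_cancer_diagnosis: 27
  nonmelanoma_only: 46
  excess_missingness: 149
  discordant_gender: 12
  discordant_sex_site: 37
indicator_counts:
  AGE_DISCORD: 250
  RARE_CANCER_YOUNG: 283
  SOURCE_INCONGRUENT: 820
  OFFTOPIC_TEXT: 56
  DUP_TELEHEALTH: 34
  DUP_SUGGESTION: 107
  DUP_EMAIL: 20
  TIMELINE_DX_LT2_TX_2TO5: 11
  TIMELINE_DX_LE5_TX_GT5: 57
  SUSPICIOUS_TIMING: 986
  SUSPICIOUS_EMAIL_ADDRESS: 166
  SUSPICIOUS_NAME: 78
burst_size: 12
burst_gap_minutes: 2
night_fraction: 0.08
legit_age_mean: 55.9
legit_age_sd: 13.1
fraud_age_mean: 41.4
fraud_age_sd: 8.2
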