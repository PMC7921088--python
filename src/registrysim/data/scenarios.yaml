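# The nine simulated scenarios: three cancer-survival levels crossed with
# Factor-X hazard ratios on cancer-specific and other-cause mortality.
defaults:
  n_cases: 5000
  n_replicates: 100
  age_mean: 70.0
  age_sd: 15.0
  p_x: 0.25
scenarios:
  A: {survival_level: low,          target_5yr_net_survival: 0.21, hr_x_cancer: 1.5, hr_x_other: 1.0}
  B: {survival_level: intermediate, target_5yr_net_survival: 0.36, hr_x_cancer: 1.5, hr_x_other: 1.0}
  C: {survival_level: high,         target_5yr_net_survival: 0.70, hr_x_cancer: 1.5, hr_x_other: 1.0}
  D: {survival_level: low,          target_5yr_net_survival: 0.21, hr_x_cancer: 3.0, hr_x_other: 1.0}
  E: {survival_level: intermediate, target_5yr_net_survival: 0.36, hr_x_cancer: 3.0, hr_x_other: 1.0}
  F: {survival_level: high,         target_5yr_net_survival: 0.70, hr_x_cancer: 3.0, hr_x_other: 1.0}
  G: {survival_level: low,          target_5yr_net_survival: 0.21, hr_x_cancer: 1.5, hr_x_other: 3.0}
  H: {survival_level: intermediate, target_5yr_net_survival: 0.36, hr_x_cancer: 1.5, hr_x_other: 3.0}
  I: {survival_level: high,         target_5yr_net_survival: 0.70, hr_x_cancer: 1.5, hr_x_other: 3.0}
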