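country: us
sex: female
start_age: 60
max_age: 100
incidence: 0.000207
detection_no_screening: {p_stage1: 0.24, p_stage2: 0.07, p_stage3: 0.28, p_stage4: 0.41}
detection_cxr: {p_stage1: 0.61, p_stage2: 0.07, p_stage3: 0.17, p_stage4: 0.15}
detection_ldct: {p_stage1: 0.9504950495049505, p_stage2: 0.009900990099009901, p_stage3: 0.0297029702970297,
  p_stage4: 0.009900990099009901}
survival: {s5_stage1: 0.75, s5_stage2: 0.53, s5_stage3: 0.41, s5_stage4: 0.07}
accuracy_cxr: {sensitivity: 0.735, specificity: 0.913}
accuracy_ldct: {sensitivity: 0.938, specificity: 0.734}
costs: {cost_screen_cxr: 42.3, cost_screen_ldct: 254.6, cost_workup: 681.0, cost_treat_stage1: 20984.0,
  cost_treat_stage2: 20984.0, cost_treat_stage3: 37987.0, cost_treat_stage4: 82601.0}
utilities: {u_stage1: 0.87, u_stage2: 0.87, u_stage3: 0.77, u_stage4: 0.57, u_cured: 0.9}
radiogenic_risk_total: 0.003
discount_rate: 0.03
wtp: 100000.0
cycle_length: 1.0
adherence: 1.0
sclc_fraction: 0.0
sensitivity_ranges:
  incidence: [0.000135, 0.000311]
  s5_stage1: [0.7, 0.85]
  s5_stage2: [0.3, 0.6]
  s5_stage3: [0.15, 0.5]
  s5_stage4: [0.01, 0.1]
  p_noscreen_stage1: [0.1, 0.6]
  p_noscreen_stage2: [0.0, 0.2]
  p_noscreen_stage3: [0.1, 0.3]
  p_noscreen_stage4: [0.3, 0.7]
  p_cxr_stage1: [0.4, 0.7]
  p_cxr_stage2: [0.0, 0.2]
  p_cxr_stage3: [0.1, 0.3]
  p_cxr_stage4: [0.1, 0.3]
  p_ldct_stage1: [0.8, 1.0]
  p_ldct_stage2: [0.0, 0.1]
  p_ldct_stage3: [0.0, 0.1]
  p_ldct_stage4: [0.0, 0.1]
  cost_screen_cxr: [21.2, 84.6]
  cost_screen_ldct: [127.3, 509.2]
  cost_workup: [340.5, 1362.0]
  cost_treat_stage1: [10492.0, 41968.0]
  cost_treat_stage2: [10492.0, 41968.0]
  cost_treat_stage3: [18994.0, 75974.0]
  cost_treat_stage4: [41301.0, 165202.0]
  sens_cxr: [0.672, 0.798]
  spec_cxr: [0.91, 0.916]
  sens_ldct: [0.906, 0.963]
  spec_ldct: [0.728, 0.739]
  u_stage1: [0.7, 0.9]
  u_stage2: [0.7, 0.9]
  u_stage3: [0.6, 0.8]
  u_stage4: [0.3, 0.6]
  u_cured: [0.7, 0.9]
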