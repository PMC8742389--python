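# Published reference values for the cohort-scaling cross-check:
# per-person incremental QALYs/LYs of LDCT relative to CXR screening for each
# 60-year-old never-smoker cohort, the national cohort sizes, and the
# published cumulative QALY/LY gains they imply (gain = round(n * delta),
# half away from zero).
cohorts:
  japan_male:
    n_individuals: 5463770
    dqaly_vs_cxr: 0.1304
    dly_vs_cxr: 0.1700
    expected_qalys_gain: 712476
    expected_lys_gain: 928841
  japan_female:
    n_individuals: 7588028
    dqaly_vs_cxr: 0.2144
    dly_vs_cxr: 0.2756
    expected_qalys_gain: 1626873
    expected_lys_gain: 2091261
  us_male:
    n_individuals: 14904704
    dqaly_vs_cxr: 0.0011
    dly_vs_cxr: 0.0016
    expected_qalys_gain: 16395
    expected_lys_gain: 23848
  us_female:
    n_individuals: 16977059
    dqaly_vs_cxr: 0.0019
    dly_vs_cxr: 0.0026
    expected_qalys_gain: 32256
    expected_lys_gain: 44140
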