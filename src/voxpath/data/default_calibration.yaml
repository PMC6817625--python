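# Default cohort calibration: two countries x two sexes.
# Vocal means/SDs follow the published group summaries; body-measure
# distributions and unreported correlations are free calibration choices.
seed: 20260905
groups:
  - sex: M
    country: BR
    n: 42
    means: {age: 22.0, height_cm: 178.0, weight_kg: 76.0, ratio: 0.72,
            speech_f0_st: -22.15, singing_f0_st: -19.71,
            speech_range_st: 11.98, singing_range_st: 14.65,
            speech_vtl_cm: 17.32, singing_vtl_cm: 16.80,
            attract_speech: 3.7, attract_singing: 3.4,
            soi_total: 35.0, liking_to_sing: 6.0}
    sds:   {age: 3.0, height_cm: 7.0, weight_kg: 10.0, ratio: 0.05,
            speech_f0_st: 2.13, singing_f0_st: 2.49,
            speech_range_st: 2.52, singing_range_st: 2.52,
            speech_vtl_cm: 0.49, singing_vtl_cm: 0.53,
            attract_speech: 0.7, attract_singing: 0.7,
            soi_total: 12.0, liking_to_sing: 2.0}
  - sex: M
    country: CZ
    n: 35
    means: {age: 22.0, height_cm: 180.0, weight_kg: 78.0, ratio: 0.72,
            speech_f0_st: -22.63, singing_f0_st: -20.51,
            speech_range_st: 11.02, singing_range_st: 14.24,
            speech_vtl_cm: 17.57, singing_vtl_cm: 17.18,
            attract_speech: 3.7, attract_singing: 3.4,
            soi_total: 35.0, liking_to_sing: 6.0}
    sds:   {age: 3.0, height_cm: 7.0, weight_kg: 10.0, ratio: 0.05,
            speech_f0_st: 1.84, singing_f0_st: 2.26,
            speech_range_st: 2.90, singing_range_st: 2.42,
            speech_vtl_cm: 0.51, singing_vtl_cm: 0.64,
            attract_speech: 0.7, attract_singing: 0.7,
            soi_total: 12.0, liking_to_sing: 2.0}
  - sex: F
    country: BR
    n: 45
    means: {age: 21.5, height_cm: 164.0, weight_kg: 60.0, ratio: 0.73,
            speech_f0_st: -13.19, singing_f0_st: -10.50,
            speech_range_st: 14.25, singing_range_st: 15.70,
            speech_vtl_cm: 14.18, singing_vtl_cm: 13.93,
            attract_speech: 3.7, attract_singing: 3.4,
            soi_total: 28.0, liking_to_sing: 6.5}
    sds:   {age: 2.5, height_cm: 6.0, weight_kg: 8.0, ratio: 0.05,
            speech_f0_st: 1.28, singing_f0_st: 2.05,
            speech_range_st: 4.23, singing_range_st: 3.25,
            speech_vtl_cm: 0.30, singing_vtl_cm: 0.38,
            attract_speech: 0.7, attract_singing: 0.7,
            soi_total: 11.0, liking_to_sing: 2.0}
  - sex: F
    country: CZ
    n: 36
    means: {age: 21.0, height_cm: 167.0, weight_kg: 61.0, ratio: 0.73,
            speech_f0_st: -13.00, singing_f0_st: -10.07,
            speech_range_st: 12.97, singing_range_st: 15.74,
            speech_vtl_cm: 14.38, singing_vtl_cm: 13.95,
            attract_speech: 3.7, attract_singing: 3.4,
            soi_total: 28.0, liking_to_sing: 6.5}
    sds:   {age: 2.5, height_cm: 6.0, weight_kg: 8.0, ratio: 0.05,
            speech_f0_st: 1.53, singing_f0_st: 2.08,
            speech_range_st: 3.55, singing_range_st: 2.96,
            speech_vtl_cm: 0.39, singing_vtl_cm: 0.34,
            attract_speech: 0.7, attract_singing: 0.7,
            soi_total: 11.0, liking_to_sing: 2.0}

# Cross-display dependence targets per sex; "attractiveness" applies to the
# structurally generated attractiveness pair.
cross_display:
  M: {f0: 0.800, range: 0.408, vtl: 0.808, attractiveness: 0.720}
  F: {f0: 0.607, range: 0.160, vtl: 0.764, attractiveness: 0.674}

# Correlations the source tables do not report; free, configurable choices.
extra_correlations:
  speech_f0_st:speech_vtl_cm: -0.5
  singing_f0_st:singing_vtl_cm: -0.5
  speech_f0_st:singing_vtl_cm: -0.4
  singing_f0_st:speech_vtl_cm: -0.4
  height_cm:weight_kg: 0.3
  height_cm:speech_vtl_cm: 0.3
  height_cm:singing_vtl_cm: 0.3
  speech_f0_st:speech_range_st: 0.2
  singing_f0_st:singing_range_st: 0.2

# Structural (standardized) coefficients of the attractiveness and
# sociosexuality equations.
structural:
  M:
    attract_speech: {weight_kg: 0.30, age: -0.20}
    attract_singing: {weight_kg: 0.25, age: -0.20}
    soi_total: {speech_f0_st: -0.25, attract_speech: 0.30}
  F:
    attract_speech: {ratio: -0.30, age: -0.15}
    attract_singing: {ratio: -0.25, age: -0.15}
    soi_total: {singing_f0_st: 0.20, attract_speech: 0.25}

liking:
  corr_attract_singing: 0.3
  scale: [1, 10]

ratings:
  target_alpha: 0.79
  rater_sd: 0.5
  raters_for_male_targets: {BR: 59, CZ: 47}
  raters_for_female_targets: {BR: 51, CZ: 46}
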