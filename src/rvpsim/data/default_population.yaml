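# Default calibration for the virtual French population aged 35-64.
#
# This is a documented APPROXIMATION assembled from public French statistics of
# the late-1990s/2000s era: stratum weights follow the national age-sex
# structure; SBP/DBP means were solved (bivariate-normal exceedance) so that
# per-stratum proportions above the historical (160/95) and current (140/90)
# hypertension thresholds match published untreated-population estimates;
# cholesterol, smoking and diabetes figures are plausible survey-era values.
# It is NOT the original survey calibration, whose moments were never published.
#
# Within-class age SD is deliberately modest (1.4 yr around the class midpoint)
# so that rejection at the class boundaries perturbs the configured moments by
# well under 1%; see docs/methods.md.
#
# Continuous block order everywhere: [age (yr), sbp (mm Hg), dbp (mm Hg),
# tchol (mmol/L)]. A stratum may specify either `covariance` (4x4) or
# `sd` + `correlation` as here.
sample_fraction: 0.04
seed: 1234
binary_mode: independent
strata:
  - sex: M
    age_class: [35, 45]
    weight: 0.177
    reference_size: 4336500
    mean: {age: 40.0, sbp: 122.3, dbp: 83.9, tchol: 5.45}
    sd: {age: 1.4, sbp: 13.5, dbp: 9.0, tchol: 1.0}
    correlation: &corr
      - [1.00, 0.25, 0.20, 0.20]
      - [0.25, 1.00, 0.70, 0.20]
      - [0.20, 0.70, 1.00, 0.18]
      - [0.20, 0.20, 0.18, 1.00]
    smoking_prevalence: 0.38
    diabetes_prevalence: 0.015
  - sex: M
    age_class: [45, 55]
    weight: 0.171
    reference_size: 4189500
    mean: {age: 50.0, sbp: 129.4, dbp: 85.7, tchol: 5.85}
    sd: {age: 1.4, sbp: 15.0, dbp: 10.0, tchol: 1.0}
    correlation: *corr
    smoking_prevalence: 0.31
    diabetes_prevalence: 0.045
  - sex: M
    age_class: [55, 65]
    weight: 0.143
    reference_size: 3503500
    mean: {age: 60.0, sbp: 138.0, dbp: 85.8, tchol: 6.00}
    sd: {age: 1.4, sbp: 17.0, dbp: 10.5, tchol: 1.0}
    correlation: *corr
    smoking_prevalence: 0.24
    diabetes_prevalence: 0.085
  - sex: F
    age_class: [35, 45]
    weight: 0.178
    reference_size: 4361000
    mean: {age: 40.0, sbp: 116.0, dbp: 76.7, tchol: 5.25}
    sd: {age: 1.4, sbp: 12.7, dbp: 10.2, tchol: 1.0}
    correlation: *corr
    smoking_prevalence: 0.31
    diabetes_prevalence: 0.010
  - sex: F
    age_class: [45, 55]
    weight: 0.175
    reference_size: 4287500
    mean: {age: 50.0, sbp: 123.7, dbp: 81.2, tchol: 5.75}
    sd: {age: 1.4, sbp: 15.0, dbp: 10.0, tchol: 1.0}
    correlation: *corr
    smoking_prevalence: 0.22
    diabetes_prevalence: 0.030
  - sex: F
    age_class: [55, 65]
    weight: 0.156
    reference_size: 3822000
    mean: {age: 60.0, sbp: 132.5, dbp: 81.8, tchol: 6.20}
    sd: {age: 1.4, sbp: 18.0, dbp: 11.0, tchol: 1.0}
    correlation: *corr
    smoking_prevalence: 0.13
    diabetes_prevalence: 0.065
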