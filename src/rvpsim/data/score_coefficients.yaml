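# SCORE 10-year fatal cardiovascular risk equations, low-risk-region coefficient
# set (Weibull baseline survival S0(age) = exp(-exp(alpha) * (age - 20)^p), with
# individual proportional-hazards term w applied as S0^exp(w)).
#
# Coefficients are the published low-risk-region estimates from the European
# SCORE project (12 pooled cohorts). Swap in a different block (e.g. a
# recalibrated or high-risk set) by editing this file; the `version` tag travels
# into run manifests so coefficient sets are traceable.
version: "score-2003-low-risk"
horizon_years: 10
age_min: 20
age_max: 90
sbp_reference: 120.0    # mm Hg
tchol_reference: 6.0    # mmol/L
endpoints:
  chd:
    male:   {alpha: -22.1, p: 4.71}
    female: {alpha: -29.8, p: 6.36}
    beta:   {smoker: 0.71, sbp: 0.018, tchol: 0.24}
  non_chd_cvd:
    male:   {alpha: -26.7, p: 5.64}
    female: {alpha: -31.0, p: 6.62}
    beta:   {smoker: 0.63, sbp: 0.022, tchol: 0.02}
# SCORE itself carries no diabetes term; diabetic status multiplies the summed
# fatal-CVD risk by a sex-specific factor (ESC chart guidance: ~2 in men, ~4 in
# women). Set apply: false to score diabetics identically to non-diabetics.
diabetes:
  apply: true
  multiplier_male: 2.0
  multiplier_female: 4.0
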