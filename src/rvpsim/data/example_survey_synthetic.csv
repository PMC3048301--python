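# Synthetic, illustrative survey table (NOT real survey data). Columns are
# proportions of each whole age-sex stratum; pct_treated + pct_known_untreated
# + pct_unknown = prevalence. Replace with a real observed table for analysis.
sex,age_class,prevalence,pct_treated,pct_known_untreated,pct_unknown
M,35-44,0.28,0.03,0.05,0.20
M,45-54,0.42,0.10,0.08,0.24
M,55-64,0.56,0.20,0.10,0.26
F,35-44,0.14,0.04,0.03,0.07
F,45-54,0.28,0.11,0.05,0.12
F,55-64,0.46,0.20,0.08,0.18
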