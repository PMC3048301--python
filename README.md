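# rvpsim

Virtual-population simulation of hypertension-treatment policies for adults
aged 35–64.

Public-health agencies need to know, before changing a guideline, how many
people a treatment rule would put on drugs and how many deaths it would
actually avert. `rvpsim` answers this with an individual-level
microsimulation: it generates a *realistic virtual population* — six age–sex
strata with jointly (multivariate-normally) distributed age, systolic and
diastolic blood pressure and total cholesterol, plus smoking and diabetes
status — scores every individual's 10-year risk of fatal cardiovascular
disease, applies competing treatment-eligibility rules, and compares their
impact and efficiency. It is aimed at epidemiologists and health-policy
modellers who want a transparent, fully seeded alternative to closed
spreadsheet models.

## The model

**Risk.** Each individual's 10-year fatal-CVD risk follows the SCORE
low-risk-region equations: a Weibull baseline survival per endpoint
(coronary and non-coronary CVD death) and sex,

```
S₀(age) = exp(−exp(α) · (age − 20)^p)
w       = β_smoker·smoker + β_SBP·(SBP − 120) + β_chol·(chol − 6)
risk    = 1 − (S₀(age+10) / S₀(age))^exp(w)
```

with total risk = CHD + non-CHD risk, multiplied by a sex-specific diabetes
factor (2 in men, 4 in women, configurable) and capped at 1. Coefficients
live in an editable YAML file (`rvpsim/data/score_coefficients.yaml`).

**Eligibility.** Three historical/current rules:

* **Scenario I** — SBP ≥ 160 or DBP ≥ 95 mm Hg (historical definition);
* **Scenario II** — SBP ≥ 140 or DBP ≥ 90 mm Hg (current definition);
* **Scenario III** — the guideline grid crossing blood-pressure grade
  (normal / high-normal / grade 1–3) with risk category (<1%, 1–5%, 5–10%,
  ≥10%): any cell other than "No" (consider drugs / drugs / drugs if
  persists) is eligible.

**Impact.** Treatment multiplies a treated individual's risk by a constant
relative risk RR = 0.83. Expected events are sums of individual risks, so
for each rule

```
NEP = NE_baseline − NE_T = (1 − RR) · Σ_{eligible} risk_i
```

(the *number of events prevented*), and efficiency is NES/NEP — eligible
subjects per event prevented, smaller = better. A replication mode
regenerates the population to give medians and inter-quartile ranges, and a
comparison layer contrasts simulated eligibility with an observed survey
table (treated-over-eligible ratios; reconstituted prevalence
`t + (1 − t)·p` folds an observed treated fraction back into the untreated
virtual population).

The shipped population calibration is a documented approximation assembled
from public French statistics (the original survey moments were never
published); see `docs/methods.md`.

## Worked example

```python
from dataclasses import replace
import rvpsim as rv

cfg = replace(rv.default_calibration(), sample_fraction=0.001, seed=42)
pop = rv.generate_population(cfg)            # ~24 500 virtual adults
scored = rv.score_population(pop)            # add 10-year fatal-CVD risk
decisions = rv.apply_scenarios(scored)       # scenarios I, II, III
summary = rv.compute_impact(scored, decisions)
totals = summary[(summary.sex == "all") & (summary.age_class == "all")]
print(totals[["scenario", "NES_over_N", "NES_over_NEP"]].to_string(index=False))
```

prints

```
scenario  NES_over_N  NES_over_NEP
       I    0.124357    193.615562
      II    0.312464    228.767054
     III    0.223451    160.847870
```

Reading: the historical threshold would treat 12.4% of 35–64-year-olds, the
current definition 31.2% (a ~2.5× inflation), and the risk-grid rule 22.3%.
Per event prevented, the grid rule "spends" ~161 eligible subjects against
~194 (historical) and ~229 (current threshold alone) — the global-risk
strategy is the most efficient of the three.

The same pipeline is available from the shell:

```bash
rvpsim run-all --seed 42 --reps 20 --outdir out/
```

writes `population.csv`, `decisions.csv`, `impact.csv`, `impact_table.csv`,
`replication.csv` and a JSON manifest (config hash + seed) sufficient to
re-run identically. `rvpsim generate/score/simulate/compare` run the stages
individually.

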