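# Methods

## Scope and model overview

`rvpsim` estimates the public-health impact and efficiency of
hypertension-treatment rules on a national population aged 35–64 by
individual-level simulation. The chain is: (1) draw a stratified virtual
population with correlated risk factors; (2) score each individual's 10-year
risk of *fatal* cardiovascular disease; (3) decide treatment eligibility
under each rule; (4) convert risks to expected events with and without
treatment. All results are expectations over the generated population; the
only randomness is in the population draw itself, controlled by one master
seed.

## The virtual population

Six strata: {men, women} × {35–44, 45–54, 55–64}. Within a stratum the
continuous block (age yr, SBP mm Hg, DBP mm Hg, total cholesterol mmol/L) is
multivariate normal with a full 4×4 covariance; smoking and diabetes are
Bernoulli with stratum prevalences. Draws violating the stratum's half-open
age interval or physiology (SBP ≤ DBP, SBP outside [70, 260] mm Hg,
cholesterol ≤ 0) are **rejected and redrawn, never clipped** — clipping
would pile mass at thresholds exactly where eligibility rules cut. If a
stratum's acceptance rate falls below 50% the generator aborts with an error
naming the stratum, since such a calibration no longer means what it says.

Binary covariates are independent of the continuous block by default — the
simplest defensible choice. An optional latent-Gaussian-threshold
mode draws a standard-normal latent per binary jointly with the continuous
block (correlations supplied per stratum) and thresholds it at the
prevalence quantile, for users who need smoking/BP correlation; the switch
isolates that assumption.

Stratum sizes are `round_half_away(reference_size × sample_fraction)`;
the default fraction is 0.04 of the reference population (~980 000
individuals), which keeps Monte-Carlo error on stratum proportions below
~0.1 percentage points while running in seconds. Per-stratum random streams
are spawned from the master seed keyed by stratum identity (sex, lower age
bound), so results are invariant to stratum order and to which strata are
present.

### The shipped calibration

The original population survey moments behind this kind of model are not
public, so the default calibration
(`src/rvpsim/data/default_population.yaml`) is an explicitly documented
approximation built from public French statistics of the survey era:

* stratum weights follow the national 35–64 age–sex structure
  (reference total 24.5 M);
* per-stratum SBP/DBP means were solved through the bivariate-normal
  exceedance equations so that the proportions above 160/95 and 140/90
  mm Hg match published untreated-population estimates for each stratum
  (SDs fixed first at plausible values, SBP–DBP correlation 0.70);
* cholesterol means/SDs and smoking/diabetes prevalences are plausible
  survey-era values; remaining correlations (0.18–0.25) are typical
  within-stratum magnitudes, kept ≥ 0.18 so that empirical covariance
  recovery is statistically meaningful at the test sample sizes.

Within-class **age SD is 1.4 yr** around the class midpoint. This is
narrower than a uniform within-class age spread; it was chosen so that
rejection at the class boundaries (±5 yr ≈ 3.6 SD) perturbs the configured
age variance and age covariances by well under 1%, keeping "the generator
reproduces its configuration" a meaningful statement. The cost is that ages
cluster near class midpoints; age-gradient results between classes are
unaffected, within-class age gradients are compressed.

### What the generator does and does not emulate

It emulates: realistic marginal BP/cholesterol levels, their covariance
(the feature that concentrates multi-factor risk in the same individuals),
age/sex risk-factor gradients, and stratum weights. It does not emulate:
treated individuals (the population is untreated by construction, so raw
hypertension prevalence is an underestimate — hence the reconstitution
step), non-normal tails (e.g. BP skewness), secular trends, regional
heterogeneity, or correlation between smoking/diabetes and the continuous
block (unless the latent mode is configured). Passing tests therefore show
the *method* behaves correctly under stated conditions, not that the shipped
numbers equal those of any particular real survey.

## Risk scoring

SCORE low-risk-region equations, Weibull form, per endpoint (CHD,
non-CHD CVD) and sex:

S₀(age) = exp(−exp(α)(age−20)^p);  w = β_smoker·smoker + β_SBP(SBP−120) +
β_chol(chol−6);  10-year risk = 1 − (S₀(age+10)/S₀(age))^exp(w).

Coefficients are shipped as data
(`score_coefficients.yaml`, version-tagged `score-2003-low-risk`) and never
hard-coded, so a recalibrated or high-risk-region set can be swapped in
without code changes. Validity range enforced: age ≥ 20 and
age + horizon ≤ 90.

SCORE has no diabetes term, but diabetic status matters clinically. Total
risk = (CHD + non-CHD) × diabetes multiplier, capped at 1. Defaults follow
risk-chart guidance: ×2 (men), ×4 (women), applied by default and
switchable off in the coefficient file (`diabetes.apply`). This is an
assumption layered on SCORE, not part of it.

Risk categories are half-open bins of total risk — low < 1% ≤ moderate
< 5% ≤ increased < 10% ≤ markedly increased — so the category function is
total; the guideline phrasing ("1–4%", "≥5%") leaves (4%, 5%) unassigned and
we resolve it into the moderate bin, with boundary behaviour pinned by
tests. Thresholds are arguments, not constants.

## Eligibility rules

BP grading takes the **higher** of the SBP band (<130, 130–139, 140–159,
160–179, ≥180) and DBP band (<85, 85–89, 90–99, 100–109, ≥110); "normal"
absorbs the optimal band since the recommendation grid has no optimal
column. All threshold comparisons are inclusive (≥), matching the printed
rules. Scenario I's "after 3 months of observation" qualifier is not
modelled — the simulation has no time dimension, so the stored BP is taken
as the post-observation value.

Scenario III uses a 4×5 grid over risk category × BP grade whose cells are
{no, consider_drugs, drugs, drugs_if_persists}; anything but "no" is
eligible ("consider drugs" and "drugs if persists" count as treatment
indications). The canonical grid is built in; a config-supplied grid can
replace it, validated for completeness.

## Impact accounting

Events are expectations: NE = Σ risk_i, with treated individuals' risks
multiplied by the constant relative risk RR = 0.83 (pooled-trial estimate
for fatal CVD, same for both sexes, assumed constant over the horizon).
Hence NEP = (1−RR)·Σ_{eligible} risk_i exactly, NES/NEP = efficiency. NEP
is linear in (1−RR) and the treated-subset event ratio NE_T/NE_baseline
recovers RR identically — both are used as algebraic self-checks. When
NEP = 0 the NES/NEP ratio is reported as undefined (NaN + flag), never a
division by zero. A Bernoulli simulator (event_i ~ Bern(risk_i)) exists as
an independent stochastic check of the expectation formula and optional
output; headline numbers never use it.

Replicate spread (median, IQR) comes from regenerating the whole population
with derived seeds — matching the interpretation of the spread as sampling
variability of the *predicted* number of events. A within-population
bootstrap mode is available as an alternative, off by default.

## Survey comparison

Observed tables arrive as CSV (`sex, age_class, prevalence, pct_treated,
pct_known_untreated, pct_unknown`, all proportions of the stratum; parts
must sum to prevalence). Reconstituted prevalence treats every treated
person as hypertensive: p_r = t + (1−t)·p. That formula is an assumption
(alternatives are pluggable); it is exact if treatment implies hypertension
and treatment status is independent of the untreated remainder's BP. The
shipped survey table is synthetic and illustrative — clearly labelled so —
because no observed values are redistributable. Treated-over-eligible
ratios use scenario III eligibility by default and are flagged undefined
where nobody is eligible.

## Numerical choices

* Covariance validation: symmetry to 1e-10, eigenvalues ≥ −1e-10; sampling
  uses an explicit Cholesky (with 1e-12 jitter) so a non-PD matrix fails
  loudly as a configuration error.
* Rejection sampling in batches of max(2·need, 1024); acceptance monitored
  cumulatively; < 50% → degenerate-calibration error.
* Stratum weights must sum to 1 within 1e-9; survey parts to prevalence
  within 1e-6.
* Empirical covariances use the 1/n normalisation so a singleton stratum
  reports zero variance instead of NaN.
* Half-away-from-zero rounding for stratum sizes (so 2.5 → 3), avoiding
  banker's-rounding surprises in tiny configurations.
* All seeds are integers; derived streams use `SeedSequence(entropy,
  spawn_key)` with identity-based keys.

## Known limitations

* **Rejection-induced coupling.** Enforcing SBP > DBP couples the retained
  pressures when the configured SBP and DBP distributions approach within
  ~2.5 SD of each other: with zero configured covariance the retained
  correlation can reach ~0.02–0.03 (quantified in the population test
  suite). This is a real property of constrained sampling, not a bug;
  diagnostics that verify the covariance *switch* therefore use
  well-separated pressure margins. At the shipped calibration (configured
  r = 0.70) the effect is negligible relative to the configured covariance.
* The population is untreated; raw prevalence underestimates real
  prevalence (addressed by reconstitution, not by modelling treated BP).
* Fatal events only; non-fatal strokes/MIs, compliance, and effect
  modifiers are out of scope, so NEP understates total benefit.
* Constant RR across risk levels and time is a simplification shared with
  the underlying trial meta-analysis.
* Ages cluster near class midpoints (see age-SD note above).

## Problem sizes used in the shipped tests

Unit tests run on ~2 400 individuals (0.01% sampling). Moment-recovery and
pattern checks use 100 000 per stratum; the Bernoulli cross-check uses
100 000 individuals × 1 000 replicates; the qualitative impact-pattern check
uses the weighted calibration at 0.4% sampling (~98 000). The acceptance
script runs the full 4% sample (~980 000). These sizes put Monte-Carlo
error comfortably inside each test's tolerance.
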