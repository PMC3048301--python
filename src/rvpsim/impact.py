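"""Public-health impact accounting: expected events, events prevented, efficiency.

Events are expectations, not sampled counts: the expected number of fatal
cardiovascular events in a group is the sum of its individuals' 10-year risks.
Treatment multiplies each treated individual's risk by a constant relative
risk (default 0.83), so

    NE_baseline = sum_i risk_i
    NE_T        = sum_i risk_i * (RR if treated_i else 1)
    NEP         = NE_baseline - NE_T = (1 - RR) * sum_{treated} risk_i

Efficiency is NES/NEP: how many eligible subjects must be treated per event
prevented (smaller = more efficient).  A Bernoulli event simulator is provided
as an independent check of the expectation formula and as optional output;
replicate runs over regenerated populations give the Monte-Carlo spread
(median and inter-quartile range) of every summary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .eligibility import apply_scenarios, default_rules
from .population import PopulationConfig, generate_population
from .score import ScoreCoefficients, load_score_coefficients, score_population

__all__ = [
    "TreatmentEffect",
    "DEFAULT_RELATIVE_RISK",
    "expected_events",
    "bernoulli_event_simulation",
    "compute_impact",
    "replicate_impact",
    "ReplicationResult",
    "impact_table",
]

# pooled trial estimate of the effect of BP-lowering drugs on fatal CVD
DEFAULT_RELATIVE_RISK = 0.83

_SUMMARY_COLUMNS = [
    "scenario", "sex", "age_class", "N", "NES", "NE_baseline", "NE_T",
    "NEP", "NES_over_N", "NES_over_NEP", "ratio_defined",
]


@dataclass(frozen=True)
class TreatmentEffect:
    """Constant multiplicative effect of treatment on individual 10-year risk."""

    relative_risk: float = DEFAULT_RELATIVE_RISK

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_risk <= 1.0:
            raise ValueError(
                f"relative risk must lie in (0, 1], got {self.relative_risk}"
            )


def expected_events(risks, treated_mask, effect: TreatmentEffect) -> float:
    """Expected event count: sum of risks, treated ones scaled by RR."""
    risks = np.asarray(risks, dtype=float)
    treated = np.asarray(treated_mask, dtype=bool)
    if risks.shape != treated.shape:
        raise ValueError(
            f"risks and treated mask differ in length ({risks.shape} vs {treated.shape})"
        )
    if risks.size and (risks.min() < 0 or risks.max() > 1):
        raise ValueError("risks must lie in [0, 1]")
    return float(np.sum(np.where(treated, risks * effect.relative_risk, risks)))


def bernoulli_event_simulation(risks, n_reps: int, seed: int) -> np.ndarray:
    """Simulate event counts by drawing each individual's event ~ Bernoulli(risk).

    Independent stochastic check of :func:`expected_events`; the analysis
    itself always uses the exact expectation.
    """
    rng = np.random.default_rng(seed)
    risks = np.asarray(risks, dtype=float)
    # one replicate at a time keeps memory flat for large populations
    return np.array(
        [rng.binomial(1, risks).sum() for _ in range(n_reps)], dtype=np.int64
    )


def _impact_row(scenario, sex, age_class, risks, eligible, rr) -> dict:
    n = risks.size
    nes = int(eligible.sum())
    ne_baseline = float(risks.sum())
    nep = float((1.0 - rr) * risks[eligible].sum())
    ne_t = ne_baseline - nep
    defined = nep > 0
    return {
        "scenario": scenario, "sex": sex, "age_class": age_class,
        "N": n, "NES": nes,
        "NE_baseline": ne_baseline, "NE_T": ne_t, "NEP": nep,
        "NES_over_N": nes / n if n else np.nan,
        "NES_over_NEP": nes / nep if defined else np.nan,
        "ratio_defined": defined,
    }


def compute_impact(
    pop: pd.DataFrame,
    decisions: pd.DataFrame,
    effect: TreatmentEffect = TreatmentEffect(),
) -> pd.DataFrame:
    """Impact summary per stratum, per sex, and overall, for each scenario.

    ``pop`` must carry ``total_risk``; ``decisions`` must cover every
    individual of the population for each scenario it contains.  Rows with
    ``sex == 'all'`` / ``age_class == 'all'`` are the marginal totals.  The
    NES/NEP ratio is reported as NaN with ``ratio_defined == False`` when no
    event is prevented.
    """
    if "total_risk" not in pop.columns:
        raise ValueError("population must be scored first (missing total_risk)")
    rr = effect.relative_risk
    rows = []
    for scenario, dec in decisions.groupby("scenario", sort=True):
        merged = pop.merge(dec[["id", "eligible"]], on="id", how="left", validate="1:1")
        if merged["eligible"].isna().any():
            raise ValueError(
                f"decisions for scenario {scenario} do not cover the population"
            )
        risks = merged["total_risk"].to_numpy()
        elig = merged["eligible"].to_numpy(dtype=bool)
        for (sex, ac), grp in merged.groupby(["sex", "age_class"], sort=True):
            rows.append(_impact_row(
                scenario, sex, ac, grp["total_risk"].to_numpy(),
                grp["eligible"].to_numpy(dtype=bool), rr,
            ))
        for sex, grp in merged.groupby("sex", sort=True):
            rows.append(_impact_row(
                scenario, sex, "all", grp["total_risk"].to_numpy(),
                grp["eligible"].to_numpy(dtype=bool), rr,
            ))
        rows.append(_impact_row(scenario, "all", "all", risks, elig, rr))
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


@dataclass(frozen=True)
class ReplicationResult:
    """Monte-Carlo spread of the impact summaries over replicate populations."""

    replicates: pd.DataFrame  # one row per (replicate, scenario)
    summary: pd.DataFrame     # median / q1 / q3 per scenario and quantity

    def iqr_width(self, scenario: str, quantity: str) -> float:
        row = self.summary[
            (self.summary["scenario"] == scenario)
            & (self.summary["quantity"] == quantity)
        ].iloc[0]
        return float(row["q3"] - row["q1"])


def replicate_impact(
    config: PopulationConfig,
    scenarios=("I", "II", "III"),
    effect: TreatmentEffect = TreatmentEffect(),
    n_reps: int = 50,
    seed: int = 0,
    coeffs: ScoreCoefficients | None = None,
    mode: str = "regenerate",
) -> ReplicationResult:
    """Regenerate the population ``n_reps`` times and track NES / NEP spread.

    ``mode='regenerate'`` (default) redraws a fresh population per replicate
    with a child seed; ``mode='bootstrap'`` draws one population and resamples
    individuals with replacement — an alternative spread estimate.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if mode not in ("regenerate", "bootstrap"):
        raise ValueError(f"unknown replication mode {mode!r}")
    coeffs = coeffs or load_score_coefficients()
    rows = []
    base = None
    if mode == "bootstrap":
        base = score_population(generate_population(replace(config, seed=seed)), coeffs)
        boot_rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    for rep in range(n_reps):
        if mode == "regenerate":
            child = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(rep,)).generate_state(1)[0]
                % (2**31)
            )
            pop = score_population(generate_population(replace(config, seed=child)), coeffs)
        else:
            pop = base.iloc[boot_rng.integers(0, len(base), size=len(base))]
            pop = pop.reset_index(drop=True).assign(id=np.arange(len(base)))
        dec = apply_scenarios(pop, scenarios, coeffs)
        imp = compute_impact(pop, dec, effect)
        tot = imp[(imp["sex"] == "all") & (imp["age_class"] == "all")]
        for _, r in tot.iterrows():
            rows.append({
                "replicate": rep, "scenario": r["scenario"], "NES": r["NES"],
                "NEP": r["NEP"], "NE_baseline": r["NE_baseline"],
                "NES_over_NEP": r["NES_over_NEP"],
            })
    reps = pd.DataFrame(rows)
    srows = []
    for scenario, grp in reps.groupby("scenario", sort=True):
        for qty in ("NES", "NEP", "NE_baseline", "NES_over_NEP"):
            q1, med, q3 = np.nanpercentile(grp[qty].to_numpy(dtype=float), [25, 50, 75])
            srows.append({
                "scenario": scenario, "quantity": qty,
                "q1": q1, "median": med, "q3": q3,
            })
    return ReplicationResult(replicates=reps, summary=pd.DataFrame(srows))


def impact_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot the impact summary into the familiar report layout.

    Rows: scenario x age class (plus 'all'); columns: men % eligible,
    women % eligible, and the overall NES/NEP of the scenario.
    """
    pct = summary[summary["sex"].isin(["M", "F"])].pivot_table(
        index=["scenario", "age_class"], columns="sex",
        values="NES_over_N", aggfunc="first",
    )
    pct = (100.0 * pct).rename(columns={"M": "men_pct_eligible", "F": "women_pct_eligible"})
    overall = summary[(summary["sex"] == "all") & (summary["age_class"] == "all")]
    ratio = overall.set_index("scenario")["NES_over_NEP"]
    out = pct.reset_index()
    out["NES_over_NEP_total"] = out["scenario"].map(ratio)
    return out
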