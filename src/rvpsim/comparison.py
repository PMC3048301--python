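"""Comparison of simulated eligibility against an observed treatment survey.

The virtual population is built from untreated individuals, so its raw
("initial") hypertension prevalence understates the real one.  A
"reconstituted" prevalence corrects this by folding back the observed treated
fraction t of each stratum, treating every treated individual as hypertensive:

    p_reconstituted = t + (1 - t) * p_virtual

The treated-over-eligible ratio then contrasts how many people a survey finds
on treatment with how many the guideline simulation says should be treated:
ratios below 1 indicate undertreatment, above 1 overtreatment.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .population import EmptyPopulationError, SEXES

__all__ = [
    "SURVEY_COLUMNS",
    "read_survey_csv",
    "validate_survey",
    "hypertension_prevalence",
    "reconstitute_prevalence",
    "treated_over_eligible",
    "compare_with_survey",
]

SURVEY_COLUMNS = (
    "sex", "age_class", "prevalence",
    "pct_treated", "pct_known_untreated", "pct_unknown",
)
AGE_CLASS_LABELS = ("35-44", "45-54", "55-64")
_SUM_TOL = 1e-6


def validate_survey(survey: pd.DataFrame) -> pd.DataFrame:
    missing = set(SURVEY_COLUMNS) - set(survey.columns)
    if missing:
        raise ValueError(f"survey table missing columns: {sorted(missing)}")
    props = survey[list(SURVEY_COLUMNS[2:])]
    if ((props < 0) | (props > 1)).any().any():
        raise ValueError("survey proportions must lie in [0, 1]")
    parts = survey[["pct_treated", "pct_known_untreated", "pct_unknown"]].sum(axis=1)
    bad = (parts - survey["prevalence"]).abs() > _SUM_TOL
    if bad.any():
        rows = survey.loc[bad, ["sex", "age_class"]].to_records(index=False).tolist()
        raise ValueError(f"treated+known+unknown != prevalence for strata {rows}")
    return survey


def read_survey_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate an observed-survey table (all values are proportions
    of the whole age-sex stratum)."""
    survey = pd.read_csv(path, comment="#")
    return validate_survey(survey)


def hypertension_prevalence(pop: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum proportion with SBP >= 140 or DBP >= 90 (current definition).

    Returns one row per (sex, age class); a stratum absent from the population
    is kept with NaN prevalence and flagged ``missing``.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot compute prevalence of an empty population")
    hyp = (pop["sbp"] >= 140.0) | (pop["dbp"] >= 90.0)
    obs = hyp.groupby([pop["sex"], pop["age_class"]]).mean()
    rows = []
    for sex in SEXES:
        for ac in AGE_CLASS_LABELS:
            p = obs.get((sex, ac), np.nan)
            rows.append({
                "sex": sex, "age_class": ac,
                "prevalence": p, "missing": not np.isfinite(p),
            })
    return pd.DataFrame(rows)


def reconstitute_prevalence(p_virtual, treated_fraction):
    """Fold an observed treated fraction back into an untreated-population
    prevalence: t + (1 - t) * p."""
    p = np.asarray(p_virtual, dtype=float)
    t = np.asarray(treated_fraction, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any((t < 0) | (t > 1)):
        raise ValueError("prevalence and treated fraction must lie in [0, 1]")
    out = t + (1.0 - t) * p
    return float(out) if out.ndim == 0 else out


def treated_over_eligible(survey: pd.DataFrame, impact_summary: pd.DataFrame,
                          scenario: str = "III") -> pd.DataFrame:
    """Observed treated share / simulated eligible share, per stratum.

    ``impact_summary`` is the per-stratum table from
    :func:`rvpsim.impact.compute_impact`; its ``NES_over_N`` column supplies
    the eligible share.  The ratio is NaN and flagged undefined where nobody
    is eligible.
    """
    validate_survey(survey)
    elig = impact_summary[
        (impact_summary["scenario"] == scenario)
        & impact_summary["sex"].isin(SEXES)
        & (impact_summary["age_class"] != "all")
    ][["sex", "age_class", "NES_over_N"]]
    merged = survey.merge(elig, on=["sex", "age_class"], how="left", validate="1:1")
    if merged["NES_over_N"].isna().any():
        missing = merged.loc[merged["NES_over_N"].isna(), ["sex", "age_class"]]
        raise ValueError(
            f"impact summary lacks strata {missing.to_records(index=False).tolist()}"
        )
    defined = merged["NES_over_N"] > 0
    merged["treated_over_eligible"] = np.where(
        defined, merged["pct_treated"] / merged["NES_over_N"], np.nan
    )
    merged["ratio_defined"] = defined
    return merged[list(SURVEY_COLUMNS[:2]) + [
        "pct_treated", "NES_over_N", "treated_over_eligible", "ratio_defined",
    ]].rename(columns={"NES_over_N": "eligible_pct_of_stratum"})


def compare_with_survey(
    pop: pd.DataFrame,
    impact_summary: pd.DataFrame,
    survey: pd.DataFrame,
    scenario: str = "III",
) -> pd.DataFrame:
    """Full comparison table over the six strata.

    Columns: virtual initial prevalence, reconstituted prevalence (using the
    survey's treated fraction), observed prevalence, simulated eligible share
    and the treated-over-eligible ratio.
    """
    validate_survey(survey)
    rvp = hypertension_prevalence(pop).rename(
        columns={"prevalence": "rvp_initial_prevalence"}
    )
    out = rvp.merge(
        survey.rename(columns={"prevalence": "observed_prevalence"}),
        on=["sex", "age_class"], how="left", validate="1:1",
    )
    out["reconstituted_prevalence"] = reconstitute_prevalence(
        out["rvp_initial_prevalence"].fillna(0.0).to_numpy(),
        out["pct_treated"].fillna(0.0).to_numpy(),
    )
    out.loc[out["missing"], "reconstituted_prevalence"] = np.nan
    ratio = treated_over_eligible(survey, impact_summary, scenario)
    out = out.merge(
        ratio[["sex", "age_class", "eligible_pct_of_stratum",
               "treated_over_eligible", "ratio_defined"]],
        on=["sex", "age_class"], how="left", validate="1:1",
    )
    return out[[
        "sex", "age_class", "rvp_initial_prevalence", "reconstituted_prevalence",
        "observed_prevalence", "eligible_pct_of_stratum",
        "pct_treated", "treated_over_eligible", "ratio_defined", "missing",
    ]]
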