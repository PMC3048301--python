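"""Treatment-eligibility rules: historical thresholds and the risk-grid rule.

Three scenarios for who should receive blood-pressure-lowering drugs:

* Scenario I  — historical definition of hypertension: SBP >= 160 or DBP >= 95.
* Scenario II — current definition: SBP >= 140 or DBP >= 90.
* Scenario III — guideline grid crossing the blood-pressure grade with the
  10-year fatal-CVD risk category: every grade 2/3 hypertensive is eligible,
  grade 1 only from moderate risk upwards, high-normal only at increased risk
  or above, normotensives never.  Any grid cell other than "no" ("consider
  drugs", "drugs", "drugs if persists") counts as eligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .score import (
    RISK_CATEGORIES,
    ScoreCoefficients,
    load_score_coefficients,
    score_population,
)

__all__ = [
    "BP_CATEGORIES",
    "RECOMMENDATIONS",
    "DEFAULT_GRID",
    "ScenarioRule",
    "default_rules",
    "bp_category",
    "eligible_scenario1",
    "eligible_scenario2",
    "eligible_scenario3",
    "apply_scenario",
    "apply_scenarios",
    "write_decisions_csv",
]

BP_CATEGORIES = ("normal", "high_normal", "grade1", "grade2", "grade3")
# "normal" here absorbs the optimal band: the grid has no separate optimal column
_SBP_CUTS = (130.0, 140.0, 160.0, 180.0)
_DBP_CUTS = (85.0, 90.0, 100.0, 110.0)

RECOMMENDATIONS = ("no", "consider_drugs", "drugs", "drugs_if_persists")

# canonical recommendation grid: rows = risk category, columns = BP category
DEFAULT_GRID: dict[tuple[str, str], str] = {
    ("low", "normal"): "no",
    ("low", "high_normal"): "no",
    ("low", "grade1"): "no",
    ("low", "grade2"): "drugs_if_persists",
    ("low", "grade3"): "drugs",
    ("moderate", "normal"): "no",
    ("moderate", "high_normal"): "no",
    ("moderate", "grade1"): "consider_drugs",
    ("moderate", "grade2"): "drugs_if_persists",
    ("moderate", "grade3"): "drugs",
    ("increased", "normal"): "no",
    ("increased", "high_normal"): "consider_drugs",
    ("increased", "grade1"): "drugs",
    ("increased", "grade2"): "drugs",
    ("increased", "grade3"): "drugs",
    ("markedly_increased", "normal"): "no",
    ("markedly_increased", "high_normal"): "consider_drugs",
    ("markedly_increased", "grade1"): "drugs",
    ("markedly_increased", "grade2"): "drugs",
    ("markedly_increased", "grade3"): "drugs",
}


class RuleError(ValueError):
    """Unknown scenario or malformed rule."""


@dataclass(frozen=True)
class ScenarioRule:
    """One eligibility rule: simple BP thresholds (I/II) or a risk grid (III)."""

    scenario: str
    sbp_threshold: float | None = None
    dbp_threshold: float | None = None
    grid: dict[tuple[str, str], str] | None = None

    def validate(self) -> None:
        if self.grid is not None:
            missing = {
                (r, b) for r in RISK_CATEGORIES for b in BP_CATEGORIES
            } - set(self.grid)
            if missing:
                raise RuleError(f"grid missing cells: {sorted(missing)}")
            bad = set(self.grid.values()) - set(RECOMMENDATIONS)
            if bad:
                raise RuleError(f"unknown recommendations: {sorted(bad)}")
        elif self.sbp_threshold is None or self.dbp_threshold is None:
            raise RuleError(f"scenario {self.scenario}: thresholds or grid required")


def default_rules() -> dict[str, ScenarioRule]:
    return {
        "I": ScenarioRule("I", sbp_threshold=160.0, dbp_threshold=95.0),
        "II": ScenarioRule("II", sbp_threshold=140.0, dbp_threshold=90.0),
        "III": ScenarioRule("III", grid=dict(DEFAULT_GRID)),
    }


def bp_category(sbp, dbp):
    """Blood-pressure category from the higher of the SBP and DBP bands.

    SBP bands: <130 normal, 130-139 high-normal, 140-159 grade 1, 160-179
    grade 2, >=180 grade 3; DBP bands: <85, 85-89, 90-99, 100-109, >=110.
    """
    s = np.asarray(sbp, dtype=float)
    d = np.asarray(dbp, dtype=float)
    if np.any(~((s > d) & (d > 0))):
        raise RuleError("blood pressure must satisfy sbp > dbp > 0")
    idx = np.maximum(np.digitize(s, _SBP_CUTS), np.digitize(d, _DBP_CUTS))
    cats = np.asarray(BP_CATEGORIES, dtype=object)[idx]
    return str(cats) if np.ndim(idx) == 0 else cats


def eligible_scenario1(sbp, dbp):
    """Historical rule: SBP >= 160 or DBP >= 95 mm Hg (inclusive)."""
    return (np.asarray(sbp) >= 160.0) | (np.asarray(dbp) >= 95.0)


def eligible_scenario2(sbp, dbp):
    """Current hypertension definition: SBP >= 140 or DBP >= 90 mm Hg."""
    return (np.asarray(sbp) >= 140.0) | (np.asarray(dbp) >= 90.0)


def eligible_scenario3(sbp, dbp, risk_cat, grid: dict | None = None):
    """Grid rule: eligible unless the (risk, BP-grade) cell says "no"."""
    if grid is None:
        grid = DEFAULT_GRID
    s = np.asarray(sbp, dtype=float)
    d = np.asarray(dbp, dtype=float)
    if np.any(~((s > d) & (d > 0))):
        raise RuleError("blood pressure must satisfy sbp > dbp > 0")
    elig_table = np.array(
        [[grid[(r, b)] != "no" for b in BP_CATEGORIES] for r in RISK_CATEGORIES]
    )
    bp_idx = np.maximum(np.digitize(s, _SBP_CUTS), np.digitize(d, _DBP_CUTS))
    r_idx = pd.Index(RISK_CATEGORIES).get_indexer(
        np.atleast_1d(np.asarray(risk_cat, dtype=object))
    )
    if (r_idx < 0).any():
        raise RuleError("unknown risk category in input")
    out = elig_table[r_idx, np.atleast_1d(bp_idx)]
    return bool(out[0]) if np.ndim(risk_cat) == 0 and np.ndim(sbp) == 0 else out


def apply_scenario(
    pop: pd.DataFrame,
    rule: ScenarioRule | str,
    coeffs: ScoreCoefficients | None = None,
) -> pd.DataFrame:
    """Decide eligibility for every individual under one scenario.

    Returns a DataFrame ``id, scenario, eligible, bp_category, risk_category``.
    The population is scored on the fly when risk columns are absent.
    """
    if isinstance(rule, str):
        rules = default_rules()
        if rule not in rules:
            raise RuleError(f"unknown scenario {rule!r}")
        rule = rules[rule]
    rule.validate()

    if len(pop) == 0:
        return pd.DataFrame(
            columns=["id", "scenario", "eligible", "bp_category", "risk_category"]
        )
    if "risk_category" not in pop.columns:
        pop = score_population(pop, coeffs or load_score_coefficients())

    sbp = pop["sbp"].to_numpy()
    dbp = pop["dbp"].to_numpy()
    if rule.grid is not None:
        elig = eligible_scenario3(sbp, dbp, pop["risk_category"].to_numpy(), rule.grid)
    else:
        elig = (sbp >= rule.sbp_threshold) | (dbp >= rule.dbp_threshold)
    return pd.DataFrame(
        {
            "id": pop["id"].to_numpy(),
            "scenario": rule.scenario,
            "eligible": np.asarray(elig, dtype=bool),
            "bp_category": bp_category(sbp, dbp),
            "risk_category": pop["risk_category"].to_numpy(),
        }
    )


def apply_scenarios(
    pop: pd.DataFrame,
    scenarios=("I", "II", "III"),
    coeffs: ScoreCoefficients | None = None,
    rules: dict[str, ScenarioRule] | None = None,
) -> pd.DataFrame:
    """Stack decisions for several scenarios into one long DataFrame."""
    rules = rules or default_rules()
    unknown = set(scenarios) - set(rules)
    if unknown:
        raise RuleError(f"unknown scenarios {sorted(unknown)}")
    if len(pop) and "risk_category" not in pop.columns:
        pop = score_population(pop, coeffs or load_score_coefficients())
    frames = [apply_scenario(pop, rules[s], coeffs) for s in scenarios]
    if not frames:
        return pd.DataFrame(
            columns=["id", "scenario", "eligible", "bp_category", "risk_category"]
        )
    return pd.concat(frames, ignore_index=True)


def write_decisions_csv(decisions: pd.DataFrame, path) -> None:
    out = decisions.copy()
    out["eligible"] = out["eligible"].astype(int)
    out.to_csv(path, index=False)
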