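"""SCORE 10-year fatal cardiovascular risk (low-risk-region equations).

The model is a Weibull proportional-hazards survival form, fitted separately
for coronary (CHD) and non-coronary cardiovascular death and by sex:

    S0(age)   = exp(-exp(alpha) * (age - 20)^p)
    w         = beta_smoker * smoker + beta_sbp * (sbp - 120)
                + beta_tchol * (tchol - 6)
    risk_10yr = 1 - (S0(age + 10) / S0(age)) ** exp(w)

Total fatal-CVD risk is the sum of the two cause-specific risks, optionally
multiplied by a sex-specific diabetes factor, capped at 1.  All functions are
vectorised over numpy arrays and accept scalars.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DomainError",
    "EndpointCoefficients",
    "ScoreCoefficients",
    "load_score_coefficients",
    "baseline_survival",
    "ten_year_cause_risk",
    "total_cvd_risk",
    "risk_category",
    "score_population",
    "RiskResult",
    "RISK_CATEGORIES",
    "DEFAULT_RISK_THRESHOLDS",
]

ENDPOINTS = ("chd", "non_chd_cvd")
RISK_CATEGORIES = ("low", "moderate", "increased", "markedly_increased")
# guideline bins for 10-year fatal-CVD risk: <1%, 1-5%, 5-10%, >=10%
DEFAULT_RISK_THRESHOLDS = (0.01, 0.05, 0.10)

_SEX_KEY = {"M": "male", "F": "female"}


class DomainError(ValueError):
    """Input outside the validity range of the risk equations."""


@dataclass(frozen=True)
class EndpointCoefficients:
    """Weibull location/shape plus log-hazard-ratio betas for one endpoint-sex."""

    alpha: float
    p: float
    beta_smoker: float
    beta_sbp: float   # per mm Hg above the SBP reference
    beta_tchol: float  # per mmol/L above the cholesterol reference

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise DomainError(f"Weibull shape p must be positive, got {self.p}")


@dataclass(frozen=True)
class ScoreCoefficients:
    version: str
    horizon: float
    age_min: float
    age_max: float
    sbp_reference: float
    tchol_reference: float
    table: dict  # (endpoint, sex) -> EndpointCoefficients
    diabetes_apply: bool
    diabetes_multiplier_male: float
    diabetes_multiplier_female: float

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise DomainError("horizon must be positive")
        if min(self.diabetes_multiplier_male, self.diabetes_multiplier_female) < 1:
            raise DomainError("diabetes multipliers must be >= 1")

    def endpoint(self, endpoint: str, sex: str) -> EndpointCoefficients:
        return self.table[(endpoint, _SEX_KEY.get(sex, sex))]

    def diabetes_multiplier(self, sex) -> np.ndarray | float:
        if not self.diabetes_apply:
            return np.where(np.asarray(sex) == "F", 1.0, 1.0)
        return np.where(
            np.asarray(sex) == "F",
            self.diabetes_multiplier_female,
            self.diabetes_multiplier_male,
        )


def load_score_coefficients(path: str | Path | None = None) -> ScoreCoefficients:
    """Load a coefficient file; with no path, the shipped low-risk set."""
    if path is None:
        raw = (resources.files("rvpsim.data") / "score_coefficients.yaml").read_text()
    else:
        raw = Path(path).read_text()
    d = yaml.safe_load(raw)
    table = {}
    for ep, block in d["endpoints"].items():
        beta = block["beta"]
        for sex in ("male", "female"):
            table[(ep, sex)] = EndpointCoefficients(
                alpha=float(block[sex]["alpha"]),
                p=float(block[sex]["p"]),
                beta_smoker=float(beta["smoker"]),
                beta_sbp=float(beta["sbp"]),
                beta_tchol=float(beta["tchol"]),
            )
    dia = d.get("diabetes", {})
    return ScoreCoefficients(
        version=str(d["version"]),
        horizon=float(d.get("horizon_years", 10)),
        age_min=float(d.get("age_min", 20)),
        age_max=float(d.get("age_max", 90)),
        sbp_reference=float(d.get("sbp_reference", 120)),
        tchol_reference=float(d.get("tchol_reference", 6)),
        table=table,
        diabetes_apply=bool(dia.get("apply", True)),
        diabetes_multiplier_male=float(dia.get("multiplier_male", 2.0)),
        diabetes_multiplier_female=float(dia.get("multiplier_female", 4.0)),
    )


def baseline_survival(age, endpoint: str, sex, coeffs: ScoreCoefficients):
    """S0(age): probability of surviving the endpoint from age 20 to ``age``."""
    age = np.asarray(age, dtype=float)
    if np.any(age < coeffs.age_min):
        raise DomainError(f"age below validity minimum {coeffs.age_min}")
    c = coeffs.endpoint(endpoint, sex if isinstance(sex, str) else "M")
    out = np.exp(-np.exp(c.alpha) * (age - 20.0) ** c.p)
    return out if out.ndim else float(out)


def _linear_predictor(c: EndpointCoefficients, sbp, tchol, smoker, coeffs):
    return (
        c.beta_smoker * np.asarray(smoker, dtype=float)
        + c.beta_sbp * (np.asarray(sbp, dtype=float) - coeffs.sbp_reference)
        + c.beta_tchol * (np.asarray(tchol, dtype=float) - coeffs.tchol_reference)
    )


def _cause_risk_one_sex(age, sbp, tchol, smoker, endpoint, sex_key, coeffs):
    c = coeffs.table[(endpoint, sex_key)]
    a = np.asarray(age, dtype=float)
    s0_now = np.exp(-np.exp(c.alpha) * (a - 20.0) ** c.p)
    s0_next = np.exp(-np.exp(c.alpha) * (a + coeffs.horizon - 20.0) ** c.p)
    w = _linear_predictor(c, sbp, tchol, smoker, coeffs)
    return 1.0 - (s0_next / s0_now) ** np.exp(w)


def ten_year_cause_risk(age, sex, sbp, tchol, smoker, endpoint: str,
                        coeffs: ScoreCoefficients):
    """Cause-specific risk of death over [age, age + horizon]."""
    age = np.asarray(age, dtype=float)
    if np.any(age < coeffs.age_min) or np.any(age + coeffs.horizon > coeffs.age_max):
        raise DomainError(
            f"age + horizon outside validity range [{coeffs.age_min}, {coeffs.age_max}]"
        )
    sex = np.asarray(sex)
    if sex.ndim == 0:
        r = _cause_risk_one_sex(age, sbp, tchol, smoker, endpoint,
                                _SEX_KEY[str(sex)], coeffs)
        return r if np.ndim(r) else float(r)
    out = np.empty(sex.shape, dtype=float)
    for code, key in _SEX_KEY.items():
        m = sex == code
        if m.any():
            out[m] = _cause_risk_one_sex(
                age[m], np.asarray(sbp, dtype=float)[m],
                np.asarray(tchol, dtype=float)[m],
                np.asarray(smoker, dtype=float)[m], endpoint, key, coeffs,
            )
    return out


@dataclass(frozen=True)
class RiskResult:
    """Cause-specific and total 10-year fatal-CVD risk (scalar or array)."""

    chd_risk: np.ndarray | float
    nonchd_risk: np.ndarray | float
    total_risk: np.ndarray | float


def total_cvd_risk(age, sex, sbp, tchol, smoker, diabetic,
                   coeffs: ScoreCoefficients) -> RiskResult:
    """Total fatal-CVD risk: CHD + non-CHD, diabetes-adjusted, capped at 1."""
    chd = ten_year_cause_risk(age, sex, sbp, tchol, smoker, "chd", coeffs)
    non = ten_year_cause_risk(age, sex, sbp, tchol, smoker, "non_chd_cvd", coeffs)
    mult = np.where(
        np.asarray(diabetic, dtype=bool), coeffs.diabetes_multiplier(sex), 1.0
    )
    total = np.minimum(1.0, (np.asarray(chd) + np.asarray(non)) * mult)
    if np.ndim(total) == 0:
        return RiskResult(float(chd), float(non), float(total))
    return RiskResult(np.asarray(chd), np.asarray(non), total)


def risk_category(total_risk, thresholds=DEFAULT_RISK_THRESHOLDS):
    """Bin total risk into the guideline categories.

    low < 1% <= moderate < 5% <= increased < 10% <= markedly_increased,
    half-open on the right so every probability gets exactly one category.
    """
    r = np.asarray(total_risk, dtype=float)
    if np.any((r < 0) | (r > 1)) or np.any(np.isnan(r)):
        raise DomainError("total risk must lie in [0, 1]")
    idx = np.digitize(r, thresholds)
    cats = np.asarray(RISK_CATEGORIES, dtype=object)[idx]
    return str(cats) if np.ndim(idx) == 0 else cats


def score_population(pop: pd.DataFrame, coeffs: ScoreCoefficients | None = None) -> pd.DataFrame:
    """Return a copy of the population with risk columns appended.

    Adds ``chd_risk``, ``nonchd_risk``, ``total_risk`` and ``risk_category``.
    """
    if coeffs is None:
        coeffs = load_score_coefficients()
    out = pop.copy()
    if len(pop) == 0:
        for col in ("chd_risk", "nonchd_risk", "total_risk"):
            out[col] = np.array([], dtype=float)
        out["risk_category"] = np.array([], dtype=object)
        return out
    res = total_cvd_risk(
        pop["age"].to_numpy(), pop["sex"].to_numpy(), pop["sbp"].to_numpy(),
        pop["tchol"].to_numpy(), pop["smoker"].to_numpy(),
        pop["diabetic"].to_numpy(), coeffs,
    )
    out["chd_risk"] = res.chd_risk
    out["nonchd_risk"] = res.nonchd_risk
    out["total_risk"] = res.total_risk
    out["risk_category"] = risk_category(res.total_risk)
    return out
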