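"""Stratified virtual-population generator with correlated risk factors.

A virtual population mimics an adult national population aged 35-64: six
age-sex strata (men/women x 35-44/45-54/55-64), each with a four-variate
normal distribution over (age, systolic BP, diastolic BP, total cholesterol)
carrying a full covariance matrix, plus stratum-specific smoking and diabetes
prevalences.  Draws that fall outside the stratum's age class or outside
physiological bounds are rejected and redrawn, never clipped, so the retained
joint distribution keeps its tail mass intact — those tails drive downstream
treatment-eligibility counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "ConfigurationError",
    "DegenerateCalibrationError",
    "EmptyPopulationError",
    "StratumSpec",
    "PopulationConfig",
    "default_calibration",
    "generate_population",
    "summarize_population",
    "load_population_config",
    "save_population_config",
    "write_population_csv",
    "read_population_csv",
]

SEXES = ("M", "F")
AGE_CLASSES = ((35, 45), (45, 55), (55, 65))
CONTINUOUS_COLUMNS = ("age", "sbp", "dbp", "tchol")
POPULATION_COLUMNS = (
    "id", "sex", "age_class", "age", "sbp", "dbp", "tchol", "smoker", "diabetic",
)

# physiological acceptance window for systolic pressure (mm Hg)
SBP_MIN, SBP_MAX = 70.0, 260.0
# rejection-sampling guard: acceptance below this fraction flags a degenerate
# calibration rather than looping forever
MIN_ACCEPTANCE = 0.5
_WEIGHT_TOL = 1e-9


class ConfigurationError(ValueError):
    """Invalid population configuration (bad covariance, weights, sizes...)."""


class DegenerateCalibrationError(RuntimeError):
    """Rejection sampling discards more than half of all draws for a stratum."""


class EmptyPopulationError(ValueError):
    """An operation that needs individuals received none."""


def age_class_label(age_class: tuple[int, int]) -> str:
    """Human label for a half-open age interval: (35, 45) -> '35-44'."""
    lo, hi = age_class
    return f"{lo}-{hi - 1}"


@dataclass(frozen=True)
class StratumSpec:
    """Calibration of one age-sex stratum.

    ``mean`` and ``covariance`` describe the joint normal law of
    (age [yr], sbp [mm Hg], dbp [mm Hg], tchol [mmol/L]); ``weight`` is the
    stratum's share of the reference population; ``reference_size`` its
    absolute head count.
    """

    sex: str
    age_class: tuple[int, int]
    mean: np.ndarray
    covariance: np.ndarray
    smoking_prevalence: float
    diabetes_prevalence: float
    weight: float
    reference_size: int = 0
    # latent-threshold mode only: correlation of the (smoking, diabetes)
    # latent normals with the continuous block, rows = (smoker, diabetic)
    binary_latent_corr: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "covariance", np.asarray(self.covariance, dtype=float))
        if self.binary_latent_corr is not None:
            object.__setattr__(
                self, "binary_latent_corr",
                np.asarray(self.binary_latent_corr, dtype=float),
            )

    @property
    def label(self) -> str:
        return f"{self.sex}{age_class_label(self.age_class)}"

    def validate(self) -> None:
        if self.sex not in SEXES:
            raise ConfigurationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        lo, hi = self.age_class
        if not lo < hi:
            raise ConfigurationError(f"empty age class {self.age_class}")
        if self.mean.shape != (4,):
            raise ConfigurationError("mean must be a 4-vector (age, sbp, dbp, tchol)")
        if self.covariance.shape != (4, 4):
            raise ConfigurationError("covariance must be 4x4")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-10):
            raise ConfigurationError(f"covariance not symmetric for {self.label}")
        if np.linalg.eigvalsh(self.covariance)[0] < -1e-10:
            raise ConfigurationError(f"covariance not positive semi-definite for {self.label}")
        if not lo <= self.mean[0] < hi:
            raise ConfigurationError(
                f"mean age {self.mean[0]} outside age class {self.age_class}"
            )
        for name in ("smoking_prevalence", "diabetes_prevalence", "weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1] for {self.label}")
        if self.reference_size < 0:
            raise ConfigurationError(f"negative reference_size for {self.label}")
        if self.binary_latent_corr is not None and self.binary_latent_corr.shape != (2, 4):
            raise ConfigurationError("binary_latent_corr must be 2x4 (smoker, diabetic) x continuous")


@dataclass(frozen=True)
class PopulationConfig:
    """Full generator configuration: strata plus sampling policy.

    ``sample_fraction`` scales every stratum's ``reference_size`` down to the
    simulated sample (default 4% of the reference population).  One master
    ``seed`` drives everything; per-stratum child seeds are derived from the
    stratum identity so results do not depend on stratum order.
    """

    strata: tuple[StratumSpec, ...]
    sample_fraction: float = 0.04
    seed: int = 0
    binary_mode: str = "independent"  # or "latent"

    def __post_init__(self) -> None:
        object.__setattr__(self, "strata", tuple(self.strata))

    def validate(self) -> None:
        if not self.strata:
            raise ConfigurationError("no strata configured")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ConfigurationError(f"sample_fraction {self.sample_fraction} outside (0, 1]")
        if self.binary_mode not in ("independent", "latent"):
            raise ConfigurationError(f"unknown binary_mode {self.binary_mode!r}")
        for s in self.strata:
            s.validate()
        total = sum(s.weight for s in self.strata)
        if abs(total - 1.0) > _WEIGHT_TOL:
            raise ConfigurationError(f"stratum weights sum to {total!r}, expected 1")
        labels = [s.label for s in self.strata]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("duplicate strata")

    def stratum_sample_size(self, spec: StratumSpec) -> int:
        return _round_half_away(spec.reference_size * self.sample_fraction)


def _round_half_away(x: float) -> int:
    """Round half away from zero (3.5 -> 4), unlike banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _stratum_seed(master: int, spec: StratumSpec) -> np.random.SeedSequence:
    # key depends only on stratum identity -> order-independent streams
    key = (SEXES.index(spec.sex), spec.age_class[0])
    return np.random.SeedSequence(entropy=master, spawn_key=key)


def _acceptance_mask(x: np.ndarray, age_class: tuple[int, int]) -> np.ndarray:
    lo, hi = age_class
    age, sbp, dbp, tchol = x.T
    return (
        (age >= lo) & (age < hi)
        & (sbp > dbp) & (dbp > 0)
        & (sbp >= SBP_MIN) & (sbp <= SBP_MAX)
        & (tchol > 0)
    )


def _sample_stratum(
    spec: StratumSpec, n: int, mode: str, seed: np.random.SeedSequence
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    try:
        np.linalg.cholesky(spec.covariance + 1e-12 * np.eye(4))
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError(f"covariance not positive definite for {spec.label}") from exc

    if mode == "latent":
        mean, cov = _extended_moments(spec)
    else:
        mean, cov = spec.mean, spec.covariance

    drawn = accepted = 0
    chunks: list[np.ndarray] = []
    need = n
    while need > 0:
        batch = max(2 * need, 1024)
        x = rng.multivariate_normal(mean, cov, size=batch, method="cholesky")
        keep = _acceptance_mask(x[:, :4], spec.age_class)
        drawn += batch
        accepted += int(keep.sum())
        chunks.append(x[keep])
        need = n - accepted
        if drawn >= 1024 and accepted / drawn < MIN_ACCEPTANCE:
            raise DegenerateCalibrationError(
                f"stratum {spec.label}: rejection sampling accepts only "
                f"{accepted / drawn:.1%} of draws; check its calibration"
            )
    x = np.concatenate(chunks)[:n]

    df = pd.DataFrame(x[:, :4], columns=list(CONTINUOUS_COLUMNS))
    if mode == "latent":
        z_smoke, z_diab = x[:, 4], x[:, 5]
        df["smoker"] = z_smoke > norm.ppf(1.0 - spec.smoking_prevalence)
        df["diabetic"] = z_diab > norm.ppf(1.0 - spec.diabetes_prevalence)
    else:
        df["smoker"] = rng.random(n) < spec.smoking_prevalence
        df["diabetic"] = rng.random(n) < spec.diabetes_prevalence
    df.insert(0, "sex", spec.sex)
    df.insert(1, "age_class", age_class_label(spec.age_class))
    return df


def _extended_moments(spec: StratumSpec) -> tuple[np.ndarray, np.ndarray]:
    """Continuous block + two unit-variance latent normals for the binaries."""
    b = spec.binary_latent_corr
    if b is None:
        b = np.zeros((2, 4))
    sd = np.sqrt(np.diag(spec.covariance))
    cross = b * sd  # corr -> covariance with the scaled continuous block
    cov = np.block([[spec.covariance, cross.T], [cross, np.eye(2)]])
    if np.linalg.eigvalsh(cov)[0] < -1e-10:
        raise ConfigurationError(
            f"latent binary correlations make the extended covariance indefinite for {spec.label}"
        )
    mean = np.concatenate([spec.mean, [0.0, 0.0]])
    return mean, cov


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Draw the full stratified population as a DataFrame.

    Columns: id, sex, age_class, age, sbp, dbp, tchol, smoker, diabetic.
    Deterministic given ``config.seed``; strata may be listed in any order.
    """
    config.validate()
    frames = []
    for spec in sorted(config.strata, key=lambda s: (s.sex, s.age_class[0])):
        n = config.stratum_sample_size(spec)
        if n == 0:
            continue
        frames.append(
            _sample_stratum(spec, n, config.binary_mode, _stratum_seed(config.seed, spec))
        )
    if not frames:
        pop = pd.DataFrame(columns=list(POPULATION_COLUMNS))
        return pop.astype({"id": int, "age": float, "sbp": float, "dbp": float,
                           "tchol": float, "smoker": bool, "diabetic": bool})
    pop = pd.concat(frames, ignore_index=True)
    pop.insert(0, "id", np.arange(len(pop)))
    return pop


def summarize_population(pop: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum empirical moments: n, means, covariance entries, prevalences.

    Covariances use the maximum-likelihood (1/n) normalisation so a singleton
    stratum reports zero variance rather than NaN.
    """
    if len(pop) == 0:
        raise EmptyPopulationError("cannot summarize an empty population")
    rows = []
    for (sex, age_class), grp in pop.groupby(["sex", "age_class"], sort=True):
        x = grp[list(CONTINUOUS_COLUMNS)].to_numpy(dtype=float)
        cov = np.cov(x, rowvar=False, ddof=0) if len(x) > 1 else np.zeros((4, 4))
        if len(x) == 1:
            cov = np.zeros((4, 4))
        row = {"sex": sex, "age_class": age_class, "n": len(grp)}
        for i, name in enumerate(CONTINUOUS_COLUMNS):
            row[f"mean_{name}"] = x[:, i].mean()
        for i, a in enumerate(CONTINUOUS_COLUMNS):
            for j, b in enumerate(CONTINUOUS_COLUMNS):
                if i <= j:
                    row[f"cov_{a}_{b}"] = cov[i, j]
        row["smoking_prevalence"] = grp["smoker"].mean()
        row["diabetes_prevalence"] = grp["diabetic"].mean()
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration and population I/O


def _spec_from_dict(d: dict) -> StratumSpec:
    mean = np.array([d["mean"][k] for k in CONTINUOUS_COLUMNS], dtype=float)
    if "covariance" in d:
        cov = np.asarray(d["covariance"], dtype=float)
    else:
        sd = np.array([d["sd"][k] for k in CONTINUOUS_COLUMNS], dtype=float)
        corr = np.asarray(d["correlation"], dtype=float)
        cov = corr * np.outer(sd, sd)
    blc = d.get("binary_latent_corr")
    return StratumSpec(
        sex=d["sex"],
        age_class=tuple(d["age_class"]),
        mean=mean,
        covariance=cov,
        smoking_prevalence=float(d["smoking_prevalence"]),
        diabetes_prevalence=float(d["diabetes_prevalence"]),
        weight=float(d["weight"]),
        reference_size=int(d.get("reference_size", 0)),
        binary_latent_corr=None if blc is None else np.asarray(blc, dtype=float),
    )


def _spec_to_dict(s: StratumSpec) -> dict:
    d = {
        "sex": s.sex,
        "age_class": list(s.age_class),
        "weight": s.weight,
        "reference_size": s.reference_size,
        "mean": {k: float(v) for k, v in zip(CONTINUOUS_COLUMNS, s.mean)},
        "covariance": [[float(v) for v in row] for row in s.covariance],
        "smoking_prevalence": s.smoking_prevalence,
        "diabetes_prevalence": s.diabetes_prevalence,
    }
    if s.binary_latent_corr is not None:
        d["binary_latent_corr"] = [[float(v) for v in row] for row in s.binary_latent_corr]
    return d


def config_from_dict(d: dict) -> PopulationConfig:
    cfg = PopulationConfig(
        strata=tuple(_spec_from_dict(sd) for sd in d["strata"]),
        sample_fraction=float(d.get("sample_fraction", 0.04)),
        seed=int(d.get("seed", 0)),
        binary_mode=d.get("binary_mode", "independent"),
    )
    cfg.validate()
    return cfg


def config_to_dict(config: PopulationConfig) -> dict:
    return {
        "sample_fraction": config.sample_fraction,
        "seed": config.seed,
        "binary_mode": config.binary_mode,
        "strata": [_spec_to_dict(s) for s in config.strata],
    }


def load_population_config(path: str | Path) -> PopulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_population_config(config: PopulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def default_calibration() -> PopulationConfig:
    """The shipped approximate calibration for French adults aged 35-64.

    Stratum moments approximate published untreated-population statistics; this
    is an explicitly documented stand-in, not the original survey calibration
    (whose moments were never published).  See the shipped
    ``data/default_population.yaml`` for the provenance notes.
    """
    ref = resources.files("rvpsim.data") / "default_population.yaml"
    return config_from_dict(yaml.safe_load(ref.read_text()))


def write_population_csv(pop: pd.DataFrame, path: str | Path) -> None:
    out = pop.copy()
    out["smoker"] = out["smoker"].astype(int)
    out["diabetic"] = out["diabetic"].astype(int)
    out.to_csv(path, index=False, columns=list(POPULATION_COLUMNS))


def read_population_csv(path: str | Path) -> pd.DataFrame:
    pop = pd.read_csv(path)
    pop["smoker"] = pop["smoker"].astype(bool)
    pop["diabetic"] = pop["diabetic"].astype(bool)
    return pop
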