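"""Generator invariants: reproducibility, rejection bounds, moment recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rvpsim.population import (
    ConfigurationError,
    DegenerateCalibrationError,
    EmptyPopulationError,
    PopulationConfig,
    StratumSpec,
    default_calibration,
    generate_population,
    load_population_config,
    read_population_csv,
    save_population_config,
    summarize_population,
    write_population_csv,
)


def _single_stratum_config(cov=None, n=1000, mean=(50.0, 130.0, 82.0, 5.8), **kw):
    cov = np.diag([1.4**2, 15.0**2, 10.0**2, 1.0**2]) if cov is None else cov
    spec = StratumSpec(
        sex="M", age_class=(45, 55), mean=np.array(mean),
        covariance=cov, smoking_prevalence=0.3, diabetes_prevalence=0.05,
        weight=1.0, reference_size=n,
    )
    return PopulationConfig(strata=(spec,), sample_fraction=1.0, seed=11, **kw)


class TestValidation:
    def test_default_calibration_is_valid_with_six_strata(self):
        cfg = default_calibration()
        cfg.validate()
        assert len(cfg.strata) == 6
        assert {(s.sex, s.age_class) for s in cfg.strata} == {
            (sex, ac) for sex in ("M", "F") for ac in ((35, 45), (45, 55), (55, 65))
        }
        assert cfg.sample_fraction == 0.04

    def test_bad_weights_rejected(self):
        cfg = default_calibration()
        bad = replace(cfg, strata=tuple(
            replace(s, weight=s.weight * 0.5) for s in cfg.strata
        ))
        with pytest.raises(ConfigurationError, match="weights"):
            bad.validate()

    def test_asymmetric_covariance_rejected(self):
        cov = np.diag([2.0, 225.0, 100.0, 1.0])
        cov[0, 1] = 5.0  # no matching [1, 0] entry
        with pytest.raises(ConfigurationError, match="symmetric"):
            _single_stratum_config(cov=cov).validate()

    def test_indefinite_covariance_rejected(self):
        cov = np.diag([1.0, 1.0, 1.0, -1.0])
        with pytest.raises(ConfigurationError):
            _single_stratum_config(cov=cov).validate()

    def test_mean_age_outside_class_rejected(self):
        spec = StratumSpec(
            sex="F", age_class=(35, 45), mean=np.array([50.0, 120.0, 75.0, 5.2]),
            covariance=np.eye(4), smoking_prevalence=0.2,
            diabetes_prevalence=0.02, weight=1.0, reference_size=10,
        )
        with pytest.raises(ConfigurationError, match="mean age"):
            PopulationConfig(strata=(spec,), sample_fraction=1.0).validate()


class TestGeneration:
    def test_zero_sample_fraction_rounding_gives_empty_population(self):
        cfg = _single_stratum_config(n=4)
        cfg = replace(cfg, sample_fraction=0.1)  # 0.4 rounds to 0
        assert len(generate_population(cfg)) == 0

    def test_half_rounds_away_from_zero(self):
        cfg = _single_stratum_config(n=5)
        cfg = replace(cfg, sample_fraction=0.5)  # 2.5 -> 3
        assert len(generate_population(cfg)) == 3

    def test_reproducible_bit_identical(self, small_config):
        a = generate_population(small_config)
        b = generate_population(small_config)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_changes_draws(self, small_config):
        a = generate_population(small_config)
        b = generate_population(replace(small_config, seed=small_config.seed + 1))
        assert not np.allclose(a["sbp"], b["sbp"])

    def test_stratum_order_does_not_matter(self, small_config):
        a = generate_population(small_config)
        shuffled = replace(small_config, strata=small_config.strata[::-1])
        b = generate_population(shuffled)
        pd.testing.assert_frame_equal(a, b)

    def test_individual_invariants_hold(self, small_population):
        pop = small_population
        assert ((pop["age"] >= 35) & (pop["age"] < 65)).all()
        assert (pop["sbp"] > pop["dbp"]).all()
        assert (pop["dbp"] > 0).all()
        assert (pop["tchol"] > 0).all()
        assert pop["id"].is_unique
        # ages respect their stratum class
        lo = pop["age_class"].str.slice(0, 2).astype(int)
        assert ((pop["age"] >= lo) & (pop["age"] < lo + 10)).all()

    def test_degenerate_calibration_raises_and_names_stratum(self):
        # mean age sits at the edge of the class -> ~half of draws rejected,
        # and sbp mean below dbp mean kills most of the rest
        spec = StratumSpec(
            sex="M", age_class=(45, 55), mean=np.array([45.0, 80.0, 79.0, 5.0]),
            covariance=np.diag([9.0, 4.0, 4.0, 0.25]),
            smoking_prevalence=0.3, diabetes_prevalence=0.05,
            weight=1.0, reference_size=2000,
        )
        cfg = PopulationConfig(strata=(spec,), sample_fraction=1.0, seed=3)
        with pytest.raises(DegenerateCalibrationError, match="M45-54"):
            generate_population(cfg)

    def test_zero_covariance_mode_decorrelates_sbp_dbp(self):
        # SBP/DBP margins ~3.5 SD apart so the sbp>dbp rejection rule is
        # essentially inactive and the diagnostic isolates the sampler
        cov = np.diag([1.4**2, 12.0**2, 8.0**2, 1.0**2])
        cfg = _single_stratum_config(cov=cov, mean=(50.0, 125.0, 75.0, 5.8),
                                     n=100_000)
        pop = generate_population(cfg)
        r = np.corrcoef(pop["sbp"], pop["dbp"])[0, 1]
        assert abs(r) < 0.02

    def test_physiological_rejection_induces_correlation_when_margins_close(self):
        """With zero configured covariance but SBP/DBP distributions only
        ~2.4 SD apart, discarding draws with sbp <= dbp couples the retained
        pressures: a real, documented property of rejection sampling."""
        cov = np.diag([1.4**2, 12.7**2, 10.2**2, 1.0**2])
        cfg = _single_stratum_config(cov=cov, mean=(50.0, 116.0, 76.7, 5.2),
                                     n=100_000)
        pop = generate_population(cfg)
        r = np.corrcoef(pop["sbp"], pop["dbp"])[0, 1]
        assert 0.01 < r < 0.05

    def test_positive_covariance_recovered(self):
        sd = np.array([1.4, 15.0, 10.0, 1.0])
        corr = np.array([
            [1.0, 0.2, 0.12, 0.15],
            [0.2, 1.0, 0.70, 0.18],
            [0.12, 0.70, 1.0, 0.15],
            [0.15, 0.18, 0.15, 1.0],
        ])
        cfg = _single_stratum_config(cov=corr * np.outer(sd, sd), n=100_000)
        pop = generate_population(cfg)
        r = np.corrcoef(pop["sbp"], pop["dbp"])[0, 1]
        assert r > 0
        assert abs(r - 0.70) < 0.05


class TestBinaryModes:
    def test_prevalence_matches_configuration(self):
        cfg = _single_stratum_config(n=100_000)
        pop = generate_population(cfg)
        assert abs(pop["smoker"].mean() - 0.3) < 0.01
        assert abs(pop["diabetic"].mean() - 0.05) < 0.005

    def test_latent_mode_preserves_prevalence_and_adds_correlation(self):
        cfg = _single_stratum_config(n=100_000)
        blc = np.array([[0.0, 0.3, 0.2, 0.0], [0.0, 0.0, 0.0, 0.0]])
        spec = replace(cfg.strata[0], binary_latent_corr=blc)
        cfg = replace(cfg, strata=(spec,), binary_mode="latent")
        pop = generate_population(cfg)
        assert abs(pop["smoker"].mean() - 0.3) < 0.01
        # smoking latent correlates with sbp -> smokers have higher sbp
        delta = pop.loc[pop["smoker"], "sbp"].mean() - pop.loc[~pop["smoker"], "sbp"].mean()
        assert delta > 1.0


class TestSummarize:
    def test_empty_population_raises(self, small_population):
        with pytest.raises(EmptyPopulationError):
            summarize_population(small_population.iloc[0:0])

    def test_single_individual_zero_covariance(self, small_population):
        summ = summarize_population(small_population.iloc[[0]])
        row = summ.iloc[0]
        assert row["n"] == 1
        assert row["mean_sbp"] == small_population.iloc[0]["sbp"]
        assert row["cov_sbp_sbp"] == 0.0
        assert row["cov_age_sbp"] == 0.0

    def test_summary_deterministic(self, small_population):
        a = summarize_population(small_population)
        b = summarize_population(small_population)
        pd.testing.assert_frame_equal(a, b)


class TestIO:
    def test_config_yaml_roundtrip(self, tmp_path, default_config):
        path = tmp_path / "cfg.yaml"
        save_population_config(default_config, path)
        loaded = load_population_config(path)
        assert loaded.sample_fraction == default_config.sample_fraction
        for a, b in zip(loaded.strata, default_config.strata):
            np.testing.assert_allclose(a.mean, b.mean)
            np.testing.assert_allclose(a.covariance, b.covariance)
            assert a.weight == b.weight

    def test_population_csv_roundtrip(self, tmp_path, small_population):
        path = tmp_path / "pop.csv"
        write_population_csv(small_population, path)
        header = path.read_text().splitlines()[0]
        assert header == "id,sex,age_class,age,sbp,dbp,tchol,smoker,diabetic"
        back = read_population_csv(path)
        pd.testing.assert_frame_equal(back, small_population, check_dtype=False)


def test_hypertension_prevalence_increases_with_age_both_sexes(default_config):
    """Under the shipped calibration, BP>=140/90 prevalence rises across the
    three age classes in each sex."""
    cfg = replace(default_config, sample_fraction=0.004, seed=5)  # ~98k total
    pop = generate_population(cfg)
    hyp = (pop["sbp"] >= 140) | (pop["dbp"] >= 90)
    prev = hyp.groupby([pop["sex"], pop["age_class"]]).mean()
    for sex in ("M", "F"):
        seq = [prev[(sex, ac)] for ac in ("35-44", "45-54", "55-64")]
        assert seq[0] < seq[1] < seq[2]
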