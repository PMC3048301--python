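"""End-to-end pipeline and command-line interface.

Stages mirror the simulation procedure: generate the virtual population,
score 10-year fatal-CVD risk, decide eligibility per scenario, tally impact
(with replicate spread), and optionally compare against an observed survey.
Every run writes CSV artifacts plus a JSON manifest (config hash, seed,
per-stage counts) sufficient to re-run identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, replace
from pathlib import Path

import click
import pandas as pd
import yaml

from . import comparison as cmp
from . import impact as imp
from .eligibility import apply_scenarios, write_decisions_csv
from .population import (
    PopulationConfig,
    config_to_dict,
    default_calibration,
    generate_population,
    load_population_config,
    read_population_csv,
    summarize_population,
    write_population_csv,
)
from .score import load_score_coefficients, score_population

__all__ = ["RunConfig", "load_run_config", "run_pipeline", "cli"]

log = logging.getLogger("rvpsim")

_SCENARIOS = ("I", "II", "III")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for one reproducible run."""

    population_config: str | None = None   # YAML path; None -> shipped default
    coefficients: str | None = None        # YAML path; None -> shipped default
    scenarios: tuple[str, ...] = _SCENARIOS
    relative_risk: float = imp.DEFAULT_RELATIVE_RISK
    n_reps: int = 0                        # 0 disables the replication stage
    seed: int = 0
    survey: str | None = None              # observed-survey CSV, optional
    outdir: str = "rvpsim_out"

    def validate(self) -> None:
        unknown = set(self.scenarios) - set(_SCENARIOS)
        if unknown:
            raise PipelineError(f"unknown scenarios {sorted(unknown)}")
        for label, path in (("population_config", self.population_config),
                            ("coefficients", self.coefficients),
                            ("survey", self.survey)):
            if path is not None and not Path(path).exists():
                raise PipelineError(f"{label} path does not exist: {path}")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        population_config=d.get("population_config"),
        coefficients=d.get("coefficients"),
        scenarios=tuple(d.get("scenarios", _SCENARIOS)),
        relative_risk=float(d.get("relative_risk", imp.DEFAULT_RELATIVE_RISK)),
        n_reps=int(d.get("n_reps", 0)),
        seed=int(d.get("seed", 0)),
        survey=d.get("survey"),
        outdir=str(d.get("outdir", "rvpsim_out")),
    )
    cfg.validate()
    return cfg


def _config_hash(pop_cfg: PopulationConfig, run_cfg: RunConfig) -> str:
    blob = json.dumps(
        {"population": config_to_dict(pop_cfg),
         "run": {"scenarios": list(run_cfg.scenarios),
                 "relative_risk": run_cfg.relative_risk,
                 "n_reps": run_cfg.n_reps, "seed": run_cfg.seed}},
        sort_keys=True,
    ).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(run_cfg: RunConfig) -> dict:
    """Execute all stages; return the manifest (also written to disk)."""
    run_cfg.validate()
    outdir = Path(run_cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "outputs": [], "seed": run_cfg.seed}
    manifest_path = outdir / "manifest.json"

    def _finish_stage(name: str, **info) -> None:
        manifest["stages"][name] = {"status": "ok", **info}

    stage = "configure"
    try:
        pop_cfg = (
            load_population_config(run_cfg.population_config)
            if run_cfg.population_config else default_calibration()
        )
        pop_cfg = replace(pop_cfg, seed=run_cfg.seed)
        coeffs = load_score_coefficients(run_cfg.coefficients)
        effect = imp.TreatmentEffect(run_cfg.relative_risk)
        manifest["config_hash"] = _config_hash(pop_cfg, run_cfg)
        manifest["coefficients_version"] = coeffs.version
        _finish_stage(stage)

        stage = "generate"
        pop = generate_population(pop_cfg)
        write_population_csv(pop, outdir / "population.csv")
        manifest["outputs"].append("population.csv")
        summarize_population(pop).to_csv(outdir / "population_summary.csv", index=False)
        manifest["outputs"].append("population_summary.csv")
        log.info("generate: %d individuals in %d strata", len(pop), pop["age_class"].nunique() * pop["sex"].nunique())
        _finish_stage(stage, n_individuals=len(pop))

        stage = "score"
        scored = score_population(pop, coeffs)
        log.info("score: mean 10-year fatal-CVD risk %.4f", scored["total_risk"].mean())
        _finish_stage(stage, mean_total_risk=float(scored["total_risk"].mean()))

        stage = "eligibility"
        decisions = apply_scenarios(scored, run_cfg.scenarios, coeffs)
        write_decisions_csv(decisions, outdir / "decisions.csv")
        manifest["outputs"].append("decisions.csv")
        counts = decisions.groupby("scenario")["eligible"].sum().to_dict()
        log.info("eligibility: %s", counts)
        _finish_stage(stage, eligible={k: int(v) for k, v in counts.items()})

        stage = "impact"
        summary = imp.compute_impact(scored, decisions, effect)
        summary.to_csv(outdir / "impact.csv", index=False)
        manifest["outputs"].append("impact.csv")
        imp.impact_table(summary).to_csv(outdir / "impact_table.csv", index=False)
        manifest["outputs"].append("impact_table.csv")
        _finish_stage(stage)

        if run_cfg.n_reps >= 2:
            stage = "replication"
            rep = imp.replicate_impact(
                pop_cfg, run_cfg.scenarios, effect,
                n_reps=run_cfg.n_reps, seed=run_cfg.seed, coeffs=coeffs,
            )
            rep.summary.to_csv(outdir / "replication.csv", index=False)
            manifest["outputs"].append("replication.csv")
            _finish_stage(stage, n_reps=run_cfg.n_reps)

        if run_cfg.survey:
            stage = "comparison"
            survey = cmp.read_survey_csv(run_cfg.survey)
            table = cmp.compare_with_survey(scored, summary, survey)
            table.to_csv(outdir / "comparison.csv", index=False)
            manifest["outputs"].append("comparison.csv")
            _finish_stage(stage)
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


# ---------------------------------------------------------------------------
# command-line interface (thin wrappers over the library)


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log per-stage counts.")
def cli(verbose: bool) -> None:
    """Virtual-population simulation of hypertension-treatment guidelines."""
    logging.basicConfig(
        level=logging.INFO if verbose else logging.WARNING,
        format="%(name)s %(levelname)s %(message)s",
    )


def _pop_config(config: str | None, seed: int | None) -> PopulationConfig:
    cfg = load_population_config(config) if config else default_calibration()
    return replace(cfg, seed=seed) if seed is not None else cfg


@cli.command()
@click.option("--config", type=click.Path(exists=True), default=None,
              help="Population calibration YAML (default: shipped calibration).")
@click.option("--seed", type=int, default=None)
@click.option("--out", type=click.Path(), required=True)
def generate(config, seed, out):
    """Generate a virtual population CSV."""
    pop = generate_population(_pop_config(config, seed))
    write_population_csv(pop, out)
    click.echo(f"wrote {len(pop)} individuals to {out}")


@cli.command()
@click.option("--population", type=click.Path(exists=True), required=True)
@click.option("--coefficients", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True)
def score(population, coefficients, out):
    """Append 10-year fatal-CVD risk columns to a population CSV."""
    pop = read_population_csv(population)
    scored = score_population(pop, load_score_coefficients(coefficients))
    scored.to_csv(out, index=False)
    click.echo(f"scored {len(scored)} individuals -> {out}")


@cli.command()
@click.option("--population", type=click.Path(exists=True), required=True)
@click.option("--scenario", "scenarios", multiple=True, default=_SCENARIOS,
              type=click.Choice(_SCENARIOS))
@click.option("--rr", type=float, default=imp.DEFAULT_RELATIVE_RISK,
              help="Relative risk of fatal CVD under treatment.")
@click.option("--outdir", type=click.Path(), required=True)
def simulate(population, scenarios, rr, outdir):
    """Eligibility decisions and impact summary for an existing population."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pop = score_population(read_population_csv(population))
    decisions = apply_scenarios(pop, scenarios)
    write_decisions_csv(decisions, outdir / "decisions.csv")
    summary = imp.compute_impact(pop, decisions, imp.TreatmentEffect(rr))
    summary.to_csv(outdir / "impact.csv", index=False)
    click.echo(f"wrote decisions.csv and impact.csv to {outdir}")


@cli.command()
@click.option("--population", type=click.Path(exists=True), required=True)
@click.option("--impact", "impact_csv", type=click.Path(exists=True), required=True)
@click.option("--survey", type=click.Path(exists=True), required=True)
@click.option("--scenario", default="III", type=click.Choice(_SCENARIOS))
@click.option("--out", type=click.Path(), required=True)
def compare(population, impact_csv, survey, scenario, out):
    """Compare simulated eligibility with an observed survey table."""
    pop = read_population_csv(population)
    summary = pd.read_csv(impact_csv)
    table = cmp.compare_with_survey(pop, summary, cmp.read_survey_csv(survey), scenario)
    table.to_csv(out, index=False)
    click.echo(f"wrote comparison to {out}")


@cli.command("run-all")
@click.option("--config", type=click.Path(exists=True), default=None,
              help="Run-config YAML; flags below override its fields.")
@click.option("--seed", type=int, default=None)
@click.option("--reps", type=int, default=None)
@click.option("--scenario", "scenarios", multiple=True, type=click.Choice(_SCENARIOS))
@click.option("--survey", type=click.Path(exists=True), default=None)
@click.option("--outdir", type=click.Path(), default=None)
def run_all(config, seed, reps, scenarios, survey, outdir):
    """Run the full pipeline and write all artifacts plus a manifest."""
    cfg = load_run_config(config) if config else RunConfig()
    updates = {}
    if seed is not None:
        updates["seed"] = seed
    if reps is not None:
        updates["n_reps"] = reps
    if scenarios:
        updates["scenarios"] = tuple(scenarios)
    if survey is not None:
        updates["survey"] = survey
    if outdir is not None:
        updates["outdir"] = outdir
    manifest = run_pipeline(replace(cfg, **updates))
    click.echo(json.dumps(manifest, indent=2))


if __name__ == "__main__":
    cli()
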