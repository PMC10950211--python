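"""Orchestration: one reproducible run from inputs (or a simulation) to
prevalence estimates, exposure probabilities, and effect estimates, with a
manifest recording config, seed, checksums, and stage timings."""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import effects as fx
from . import exposure as xp
from . import io
from . import prevalence as pv
from .exceptions import ConfigurationError, PipelineError
from .simulate import SimulationConfig, PrevalenceSpec, simulate_dataset

logger = logging.getLogger(__name__)

DESIGNS = ("lagged_dv", "first_diff", "did", "psm", "placebo")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; CLI flags override file values."""

    output_dir: str = "epivote_run"
    seed: int = 0
    # either a simulation...
    simulate: bool = True
    simulation: dict = field(default_factory=dict)
    # ...or paths to input tables
    population: str | None = None
    deaths: str | None = None
    ifr: str | None = None
    panel: str | None = None
    covariates: str | None = None
    # analysis options
    window: str = "six_week"
    extrapolation: str = "auto"
    transform: str = "decile"
    designs: tuple[str, ...] = ("lagged_dv", "first_diff", "did", "psm")
    caliper: float = 0.025
    network_size: int = 15
    thresholds: tuple[float, ...] = (0.30, 0.50)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.window not in ("six_week", "four_week"):
            raise ConfigurationError("window must be six_week or four_week")
        bad = set(self.designs) - set(DESIGNS)
        if bad:
            raise ConfigurationError(f"unknown designs: {sorted(bad)}")
        if not self.simulate:
            for name in ("population", "deaths", "ifr", "panel", "covariates"):
                p = getattr(self, name)
                if p is None:
                    raise ConfigurationError(f"input path '{name}' required")
                if not Path(p).exists():
                    raise ConfigurationError(f"input file not found: {p}")

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        if "prevalence_spec" in kwargs and isinstance(kwargs["prevalence_spec"], dict):
            kwargs["prevalence_spec"] = PrevalenceSpec(**kwargs["prevalence_spec"])
        kwargs.setdefault("seed", self.seed)
        return SimulationConfig(**kwargs)


@dataclass
class PipelineResult:
    prevalence: pd.DataFrame
    exposure_counts: pd.DataFrame
    estimates: dict[str, fx.EffectEstimate]
    manifest: dict
    output_dir: Path


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("data")
def _load_data(config: RunConfig):
    if config.simulate:
        sim = simulate_dataset(config.simulation_config(), windows=(config.window,))
        return {
            "population": sim.census_population,
            "deaths": sim.deaths[config.window],
            "ifr": sim.ifr,
            "panel": sim.panel,
            "covariates": sim.covariates.drop(columns=["_urbanicity"], errors="ignore"),
            "truth": sim.truth,
        }
    return {
        "population": io.read_table(config.population, "population"),
        "deaths": io.read_table(config.deaths, "deaths"),
        "ifr": io.read_table(config.ifr, "ifr"),
        "panel": io.read_table(config.panel, "election_panel"),
        "covariates": io.read_table(config.covariates, "covariates"),
        "truth": None,
    }


@_stage("prevalence")
def _prevalence_stage(config: RunConfig, data: dict):
    population = data["population"]
    deaths = data["deaths"]
    last_death_year = int(deaths["year"].max())
    if int(population["year"].max()) < last_death_year:
        population, _ = pv.extrapolate_population(
            population, method=config.extrapolation, through=last_death_year
        )
    fit = pv.estimate_prevalence(population, deaths, data["ifr"])
    transform = pv.transform_prevalence(fit.estimates, config.transform)
    baseline = pv.compute_baseline_mortality(
        fit.hazards, population, year=last_death_year
    )
    return fit, transform, baseline


@_stage("exposure")
def _exposure_stage(config: RunConfig, fit: pv.PrevalenceFit):
    return xp.count_exceeding(
        fit.estimates, k=config.network_size, thresholds=tuple(config.thresholds)
    )


@_stage("effects")
def _effects_stage(config: RunConfig, data, fit, transform, baseline):
    panel, covariates = data["panel"], data["covariates"]
    dm = fx.build_design_matrix(panel, covariates, transform, baseline)
    out: dict[str, fx.EffectEstimate] = {}
    treated = None
    if {"did", "psm"} & set(config.designs):
        vals = fit.estimates.set_index("municipality_id")["pi_hat"].sort_index()
        treated = fx.define_treatment(vals)
    for design in config.designs:
        if design == "lagged_dv":
            out[design] = fx.fit_lagged_dv(dm)
        elif design == "first_diff":
            out[design] = fx.fit_first_difference(panel, covariates, transform, baseline)
        elif design == "did":
            out[design] = fx.fit_did(panel, treated)
        elif design == "psm":
            matched = fx.propensity_match(
                dm, treated, caliper=config.caliper, seed=config.seed
            )
            out[design] = fx.matched_estimate(dm, matched)
        elif design == "placebo":
            out[design] = fx.placebo_test(panel, covariates, transform, baseline)
    return out


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage, write outputs + manifest, return the result bundle."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    data = _load_data(config)
    timings["data"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fit, transform, baseline = _prevalence_stage(config, data)
    timings["prevalence"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    exposure_counts = _exposure_stage(config, fit)
    timings["exposure"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    estimates = _effects_stage(config, data, fit, transform, baseline)
    timings["effects"] = time.perf_counter() - t0

    paths = {}
    paths["prevalence"] = io.write_table(fit.estimates, outdir / "prevalence.csv")
    paths["exposure"] = io.write_table(exposure_counts, outdir / "exposure_counts.csv")
    coef_rows = []
    for design, est in estimates.items():
        coef_rows.append(
            {
                "design": design,
                "transform": est.transform,
                "coefficient": est.coefficient,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "p_value": est.p_value,
                "n_obs": est.n_obs,
                "r_squared": est.r_squared,
                "notes": est.notes,
            }
        )
    paths["effects"] = io.write_table(pd.DataFrame(coef_rows), outdir / "effects.csv")

    report = outdir / "report.txt"
    with report.open("w") as fh:
        fh.write("epivote run report\n==================\n\n")
        for design, est in estimates.items():
            fh.write(
                f"{design:12s} transform={est.transform:10s} "
                f"coef={est.coefficient:+.4f}  se={est.se:.4f}  "
                f"p={est.p_value:.4f}  n={est.n_obs}\n"
            )

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
        "outputs": {k: str(p) for k, p in paths.items()},
        "checksums": {k: io.file_checksum(p) for k, p in paths.items()},
    }
    io.write_manifest(outdir / "manifest.json", manifest)
    return PipelineResult(
        prevalence=fit.estimates,
        exposure_counts=exposure_counts,
        estimates=estimates,
        manifest=manifest,
        output_dir=outdir,
    )
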