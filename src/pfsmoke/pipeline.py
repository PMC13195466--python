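"""End-to-end pipeline: configuration schema and stage orchestration.

A single validated configuration drives every stage in dependency order:

    simulate -> calibrate -> emissions -> attribute -> fuse -> evaluate
             -> aggregate

Stages communicate only through serialized artifacts (NetCDF / CSV /
JSON) under the output directory, and every run writes a machine-readable
manifest stamped with the configuration hash and the global seed.  One
global seed deterministically derives per-stage seeds, so a rerun with the
same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator
from shapely.geometry import box

from . import burnarea, synthetic
from .aggregation import (
    compute_coverage_weights,
    exceedance_stats,
    period_summary,
    pf_share,
    weighted_daily_mean,
)
from .emissions import EmissionFactorTable, compute_emissions
from .errors import PFSmokeError
from .evaluation import EMERY_CRITERIA, EMERY_GOALS, benchmark_flags, compute_stats, kfold_cv
from .fields import SPECIES, TOTAL, make_dates
from .fusion import FusionConfig, exclude_near_road, run_fusion, _collocate
from .grid import GridDefinition
from .io import (
    read_regions_geojson,
    write_dataset,
    write_events,
    write_observations,
    write_pair,
    write_sites,
)
from .seasons import DEFAULT_SEASONS

logger = logging.getLogger("pfsmoke")

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline", "build_study"]


class PipelineStageError(PFSmokeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Model):
    n_rows: int = 30
    n_cols: int = 30
    cell_size_km: float = 12.0

    def build(self) -> GridDefinition:
        return GridDefinition(self.n_rows, self.n_cols, self.cell_size_km)


class PeriodConfig(_Model):
    start: str = "2020-09-15"
    n_days: int = Field(default=120, ge=1)


class KernelConfig(_Model):
    scale_km: float = 18.0
    wind_sd_km: float = 24.0
    mixing_height_m: float = 12_000.0

    def build(self) -> synthetic.KernelParams:
        return synthetic.KernelParams(self.scale_km, self.wind_sd_km, self.mixing_height_m)


class ModelErrorConfig(_Model):
    sigma: float = 0.30
    corr_km: float = 100.0
    ar1: float = 0.8

    def build(self) -> synthetic.ModelErrorParams:
        return synthetic.ModelErrorParams(self.sigma, self.corr_km, self.ar1)


class GeneratorConfig(_Model):
    mean_daily_events: float = 10.0
    median_area_acres: float = 50.0
    area_sigma_log: float = 1.2
    prescribed_fraction: float = 0.7
    private_fraction: float = 0.84
    seasonal_weights: dict[str, float] = Field(
        default_factory=lambda: dict(synthetic.DEFAULT_SEASONAL_WEIGHTS)
    )
    min_detectable_area: float = 1.18
    overreport_factor: float = 0.66
    miss_probability: float = 0.2
    permit_coverage: float = 0.5
    permit_mode: str = "region"
    n_total_pm_sites: int = 36
    n_speciation_sites: int = 12
    near_road_fraction: float = 0.1
    noise_sd: float = 0.10
    background: dict[str, float] = Field(
        default_factory=lambda: dict(synthetic.DEFAULT_BACKGROUND)
    )
    model_biases: dict[str, float] = Field(
        default_factory=lambda: dict(synthetic.DEFAULT_MODEL_BIASES)
    )
    kernel: KernelConfig = Field(default_factory=KernelConfig)
    model_error: ModelErrorConfig = Field(default_factory=ModelErrorConfig)


class EmissionFactorsConfig(_Model):
    factors: dict[str, float] = Field(
        default_factory=lambda: dict(EmissionFactorTable().factors)
    )
    fuel_load_tons_per_acre: float = 24.7
    consumption_fraction: float = 1.0

    @field_validator("factors")
    @classmethod
    def _all_species_present(cls, factors: dict[str, float]) -> dict[str, float]:
        missing = [sp for sp in SPECIES if sp not in factors]
        if missing:
            raise ValueError(f"missing emission factor for species: {', '.join(missing)}")
        return factors

    def build(self) -> EmissionFactorTable:
        return EmissionFactorTable(
            factors=dict(self.factors),
            fuel_load_tons_per_acre=self.fuel_load_tons_per_acre,
            consumption_fraction=self.consumption_fraction,
        )


class CalibrationConfig(_Model):
    fit_intercept: bool = False


class FusionSettings(_Model):
    polynomial_degree: int = 2
    min_pairs_per_day: int = 5
    idw_power: float = 2.0
    idw_radius_km: float = 300.0
    denom_floor: float = 0.01
    ratio_cap: float = 10.0
    concentration_floor: float = 0.01

    def build(self) -> FusionConfig:
        return FusionConfig(**self.model_dump())


class EvaluationConfig(_Model):
    kfold: int = 10
    mnb_obs_floor: float = 1.0


class AggregationConfig(_Model):
    exceedance_threshold: float = 3.5
    clamp_negative: bool = False
    regions_geojson: str | None = None


class PipelineConfig(_Model):
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    grid: GridConfig = Field(default_factory=GridConfig)
    period: PeriodConfig = Field(default_factory=PeriodConfig)
    generator: GeneratorConfig = Field(default_factory=GeneratorConfig)
    emission_factors: EmissionFactorsConfig = Field(default_factory=EmissionFactorsConfig)
    calibration: CalibrationConfig = Field(default_factory=CalibrationConfig)
    fusion: FusionSettings = Field(default_factory=FusionSettings)
    evaluation: EvaluationConfig = Field(default_factory=EvaluationConfig)
    aggregation: AggregationConfig = Field(default_factory=AggregationConfig)

    def hash(self) -> str:
        canonical = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def with_overrides(self, overrides: dict[str, str]) -> "PipelineConfig":
        """Apply dotted ``key=value`` overrides (values parsed as YAML)."""
        import yaml

        data = self.model_dump()
        for dotted, raw in overrides.items():
            node = data
            *path, leaf = dotted.split(".")
            for part in path:
                node = node[part]
            node[leaf] = yaml.safe_load(raw)
        return PipelineConfig.model_validate(data)


def _stage_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def build_study(config: PipelineConfig) -> synthetic.SyntheticStudy:
    """Generate the full synthetic study described by the configuration."""
    g = config.generator
    seeds = _stage_seeds(config.seed)
    grid = config.grid.build()
    dates = make_dates(config.period.start, config.period.n_days)
    table = config.emission_factors.build()

    truth = synthetic.generate_burn_truth(
        grid,
        n_days=config.period.n_days,
        seasonal_weights=g.seasonal_weights,
        mean_daily_events=g.mean_daily_events,
        median_area_acres=g.median_area_acres,
        area_sigma_log=g.area_sigma_log,
        prescribed_fraction=g.prescribed_fraction,
        private_fraction=g.private_fraction,
        start=config.period.start,
        seed=seeds[0],
    )
    satellite = synthetic.degrade_to_satellite(
        truth, g.min_detectable_area, g.overreport_factor, g.miss_probability, seed=seeds[1]
    )
    permits = synthetic.sample_permits(truth, g.permit_coverage, seed=seeds[2],
                                       mode=g.permit_mode, grid=grid)

    pf_events = truth[truth["burn_type"] == "prescribed"]
    other_events = truth[truth["burn_type"] != "prescribed"]
    pf_emissions = compute_emissions(pf_events, table, grid, dates)
    other_emissions = compute_emissions(other_events, table, grid, dates)

    truth_pair = synthetic.simulate_concentration_fields(
        grid,
        pf_emissions,
        background=g.background,
        kernel=g.kernel.build(),
        other_emissions=other_emissions,
        seed=seeds[3],
    )
    model_pair = synthetic.bias_model_fields(
        truth_pair, g.model_biases, g.model_error.build(), seed=seeds[4]
    )
    sites = synthetic.generate_sites(
        grid, g.n_total_pm_sites, g.n_speciation_sites, g.near_road_fraction, seed=seeds[5]
    )
    observations = synthetic.generate_observations(
        truth_pair.all_emissions, sites, g.noise_sd, seed=seeds[5]
    )
    return synthetic.SyntheticStudy(
        grid=grid,
        dates=dates,
        seasons=DEFAULT_SEASONS,
        truth_events=truth,
        satellite_events=satellite,
        permit_events=permits,
        pf_emissions=pf_emissions,
        other_emissions=other_emissions,
        truth_pair=truth_pair,
        model_pair=model_pair,
        sites=sites,
        observations=observations,
    )


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "artifacts": {},
        "results": {},
    }

    def stage(name: str):
        logger.info("[%s] running", name)

        class _Ctx:
            def __enter__(self_inner):
                return None

            def __exit__(self_inner, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineStageError(name, exc) from exc
                logger.info("[%s] done", name)

        return _Ctx()

    with stage("simulate"):
        study = build_study(config)
        write_events(study.truth_events, out / "burn_truth.csv")
        write_events(study.satellite_events, out / "burn_satellite.csv")
        write_events(study.permit_events, out / "burn_permits.csv")
        write_sites(study.sites, out / "sites.csv")
        write_observations(study.observations, out / "observations.csv")
        write_pair(study.truth_pair, out / "fields_truth.nc")
        write_pair(study.model_pair, out / "fields_model.nc")
        manifest["artifacts"]["simulate"] = [
            "burn_truth.csv", "burn_satellite.csv", "burn_permits.csv",
            "sites.csv", "observations.csv", "fields_truth.nc", "fields_model.nc",
        ]

    with stage("calibrate"):
        # Calibrate only where permit reporting is complete: satellite keys
        # outside the permit-covered region would enter as false zeros.
        sat_for_fit = study.satellite_events
        if config.generator.permit_mode == "region":
            n_covered = int(np.ceil(config.generator.permit_coverage * study.grid.n_cols))
            sat_for_fit = sat_for_fit[sat_for_fit["col"] < n_covered]
        pairs = burnarea.match_pairs(sat_for_fit, study.permit_events, study.grid)
        model = burnarea.fit_scaling(pairs, fit_intercept=config.calibration.fit_intercept)
        calibrated = burnarea.apply_calibration(study.satellite_events, model)
        (out / "calibration.json").write_text(json.dumps(model.as_dict(), indent=2))
        write_events(calibrated, out / "burn_calibrated.csv")
        summary = burnarea.burn_summary(calibrated, study.seasons)
        summary.to_csv(out / "burn_summary.csv", index=False)
        manifest["artifacts"]["calibrate"] = [
            "calibration.json", "burn_calibrated.csv", "burn_summary.csv",
        ]
        manifest["results"]["calibration_slope"] = model.slope
        manifest["results"]["calibration_r_squared"] = model.r_squared

    with stage("emissions"):
        table = config.emission_factors.build()
        pf_cal = calibrated[calibrated["burn_type"] == "prescribed"]
        emis = compute_emissions(pf_cal, table, study.grid, study.dates)
        write_dataset(emis, out / "emissions_calibrated.nc", study.grid)
        manifest["artifacts"]["emissions"] = ["emissions_calibrated.nc"]
        manifest["results"]["pf_pm25_emitted_tons"] = float(
            sum(emis[sp].sum().item() for sp in SPECIES)
        )

    fusion_config = config.fusion.build()
    with stage("fuse"):
        fused = run_fusion(study.model_pair, study.observations, study.sites, fusion_config)
        write_dataset(
            fused["delta_sim"], out / "delta_pf_sim.nc", study.grid
        )
        fused_out = fused["fused_species"].copy()
        fused_out[TOTAL] = fused["fused_total"]
        write_dataset(fused_out, out / "fused_fields.nc", study.grid)
        delta_out = fused["fused_delta_species"].copy()
        delta_out[TOTAL] = fused["fused_delta_total"]
        write_dataset(delta_out, out / "fused_delta_pf.nc", study.grid)
        manifest["artifacts"]["fuse"] = [
            "delta_pf_sim.nc", "fused_fields.nc", "fused_delta_pf.nc",
        ]

    with stage("evaluate"):
        obs = exclude_near_road(study.observations, study.sites)
        sim_total = study.model_pair.all_emissions[TOTAL]
        coll = _collocate(obs, study.sites, sim_total, TOTAL)
        fused_at = fused["fused_total"].values[
            coll["day"].to_numpy(), coll["row"].to_numpy(int), coll["col"].to_numpy(int)
        ]
        floor = config.evaluation.mnb_obs_floor
        stats = {
            "sim": compute_stats(coll["sim"].to_numpy(), coll["value"].to_numpy(), floor),
            "fused": compute_stats(fused_at, coll["value"].to_numpy(), floor),
        }
        cv = kfold_cv(
            sim_total, study.observations, study.sites, study.grid,
            k=config.evaluation.kfold, seed=config.seed, config=fusion_config,
        )
        payload = {
            name: s.as_dict() for name, s in stats.items()
        }
        payload["cv_pooled_sim"] = cv.pooled_sim.as_dict()
        payload["cv_pooled_fused"] = cv.pooled_fused.as_dict()
        payload["benchmarks"] = {
            "fused_goals": benchmark_flags(stats["fused"], EMERY_GOALS),
            "fused_criteria": benchmark_flags(stats["fused"], EMERY_CRITERIA),
        }
        (out / "evaluation.json").write_text(json.dumps(payload, indent=2))
        manifest["artifacts"]["evaluate"] = ["evaluation.json"]
        manifest["results"]["fused_nmb_pct"] = stats["fused"].nmb
        manifest["results"]["sim_nmb_pct"] = stats["sim"].nmb
        manifest["results"]["cv_fused_rmse"] = cv.pooled_fused.rmse
        manifest["results"]["cv_sim_rmse"] = cv.pooled_sim.rmse

    with stage("aggregate"):
        if config.aggregation.regions_geojson:
            regions = read_regions_geojson(config.aggregation.regions_geojson)
        else:
            regions = [("domain", box(*study.grid.extent_km()))]
        rows = []
        exceed = None
        for name, poly in regions:
            weights = compute_coverage_weights(study.grid, poly, name)
            pf_daily = weighted_daily_mean(fused["fused_delta_total"], weights)
            ambient_daily = weighted_daily_mean(fused["fused_total"], weights)
            if config.aggregation.clamp_negative:
                pf_daily = pf_daily.clip(lower=0.0)
            _, share_pct = pf_share(pf_daily, ambient_daily)
            summary = period_summary(pf_daily, study.seasons)
            summary.insert(0, "region", name)
            summary["share_pct"] = share_pct
            rows.append(summary)
            if exceed is None:
                exceed = exceedance_stats(
                    fused["fused_delta_total"],
                    config.aggregation.exceedance_threshold,
                    pf_daily,
                )
                manifest["results"]["pf_pm25_mean"] = float(pf_daily.mean())
                manifest["results"]["pf_share_pct"] = share_pct
                manifest["results"]["exceedance_cell_day_fraction"] = exceed.cell_day_fraction
        pd.concat(rows, ignore_index=True).to_csv(out / "aggregation.csv", index=False)
        manifest["artifacts"]["aggregate"] = ["aggregation.csv"]

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
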