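"""End-to-end orchestration: simulate -> composite/features -> train ->
predict -> resilience -> trend, with a content-hashed artifact manifest.

Every random draw descends from the single root seed through named
substreams, so identical (config, seed) reruns produce identical artifacts
for the deterministic stages. Stages can be toggled; a disabled upstream
stage is resumed from its artifacts on disk when possible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bgi_model, features, resilience, spectral, synthetic, trend
from .io import read_json, read_tiff, sha256_of, write_json, write_tiff
from .synthetic import WorldConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run"]

STAGES = ("simulate", "features", "train", "predict", "resilience", "trend")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Configuration of one pipeline run; see WorldConfig for the generator."""

    world: WorldConfig = field(default_factory=WorldConfig)
    scenario: str = "loss_of_resistance"
    outdir: str = "rangeres_run"
    stages: tuple[str, ...] = STAGES
    n_plots: int = 256
    survey_years: tuple[int, ...] = (2016, 2018)
    survey_cell_size: int = 2  # survey-cell grid is finer than the analysis grid
    holdout_fraction: float = 0.25
    cv_repeats: int = 10
    reference_year: int = 2016
    block: int = 7
    k_shocks: int = 4
    final_years: tuple[int, ...] | None = None

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @property
    def seed(self) -> int:
        return self.world.seed

    def to_yaml(self, path) -> Path:
        d = dataclasses.asdict(self)
        path = Path(path)
        path.write_text(yaml.safe_dump(d, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        world = d.pop("world", {})
        for key in ("years", "shock_years", "soil_endmember", "veg_endmember"):
            if key in world and world[key] is not None:
                world[key] = tuple(world[key])
        cfg = cls(world=WorldConfig(**world), **_tuplify(d))
        return cfg


def _tuplify(d: dict) -> dict:
    for key in ("stages", "survey_years", "final_years"):
        if d.get(key) is not None:
            d[key] = tuple(d[key])
    return d


def _record(manifest, stage, name, path):
    manifest["artifacts"].setdefault(stage, {})[name] = {
        "path": str(path),
        "sha256": sha256_of(path),
    }


def run(config: RunConfig) -> dict:
    """Execute the configured stages and return the artifact manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "scenario": config.scenario, "artifacts": {}}
    cfg_path = config.to_yaml(out / "config.yaml")
    _record(manifest, "config", "config", cfg_path)
    state: dict = {}
    t0 = time.time()

    for stage in STAGES:
        if stage not in config.stages:
            continue
        start = time.time()
        _STAGE_FUNCS[stage](config, out, state, manifest)
        logger.info("stage %s finished in %.1f s", stage, time.time() - start)

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    write_json(out / "manifest.json", manifest)
    return manifest


def _need(state, key, config, out, stage_hint):
    if key in state:
        return state[key]
    loader = _LOADERS.get(key)
    if loader is not None:
        try:
            state[key] = loader(config, out)
            return state[key]
        except FileNotFoundError:
            pass
    raise PipelineError(f"missing upstream artifact {key!r}: rerun stage {stage_hint!r} first")


# --- stages -----------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, state: dict, manifest: dict):
    world = synthetic.generate_world(config.world, config.scenario)
    state.update(world)
    truth, rainfall, cover = world["truth"], world["rainfall"], world["cover"]
    p = write_tiff(
        out / "truth.tif",
        np.stack(
            [
                truth.baseline,
                truth.susceptibility,
                truth.recovery_rate,
                truth.phase,
                truth.human_density,
                truth.livestock_density,
                truth.designation.astype(float),
            ]
        ),
        band_names=[
            "baseline",
            "susceptibility",
            "recovery_rate",
            "phase",
            "human_density",
            "livestock_density",
            "designation",
        ],
    )
    _record(manifest, "simulate", "truth", p)
    p = out / "rainfall.csv"
    rainfall.to_frame().to_csv(p, index=False)
    _record(manifest, "simulate", "rainfall", p)
    p = write_tiff(out / "cover_true.tif", cover.cover)
    _record(manifest, "simulate", "cover_true", p)


def _stage_features(config: RunConfig, out: Path, state: dict, manifest: dict):
    truth = _need(state, "truth", config, out, "simulate")
    rainfall = _need(state, "rainfall", config, out, "simulate")
    cover = _need(state, "cover", config, out, "simulate")
    wc = config.world
    dates, stacks = [], {"evi": [], "bsi": [], "msavi": []}
    for year in wc.years:
        for scene in synthetic.render_year(cover, truth, wc, int(year)):
            dates.append(scene.date)
            stacks["evi"].append(spectral.compute_evi(scene).astype(np.float32))
            stacks["bsi"].append(spectral.compute_bsi(scene).astype(np.float32))
            stacks["msavi"].append(spectral.compute_msavi(scene).astype(np.float32))
    series = {
        name: spectral.fill_gaps(spectral.IndexSeries(name, np.array(dates), np.stack(vals)))
        for name, vals in stacks.items()
    }
    state["index_series"] = series
    table = features.build_feature_table(series, rainfall, wc.years, config=wc)
    state["feature_table"] = table
    p = out / "features.parquet"
    table.to_parquet(p, index=False)
    _record(manifest, "features", "feature_table", p)


def _stage_train(config: RunConfig, out: Path, state: dict, manifest: dict):
    truth = _need(state, "truth", config, out, "simulate")
    rainfall = _need(state, "rainfall", config, out, "simulate")
    cover = _need(state, "cover", config, out, "simulate")
    table = _need(state, "feature_table", config, out, "features")
    wc = config.world

    # Survey-site stratification on the survey-cell grid: long-term mean
    # rainfall, greenness (mean vegetated fraction as a stand-in for mean
    # NDVI), and a grassland/woodland layer proxied by phenology timing so
    # the three layers are not collinear.
    cell = config.survey_cell_size
    rain_mean = rainfall.annual_totals().mean(axis=0)
    cr = (np.arange(wc.grid_rows // cell) * cell + cell // 2) * wc.rain_rows // wc.grid_rows
    cc = (np.arange(wc.grid_cols // cell) * cell + cell // 2) * wc.rain_cols // wc.grid_cols
    rain_cells = rain_mean[cr[:, None], cc[None, :]]
    green = 1.0 - resilience.aggregate_to_coarse(cover.cover.mean(axis=0), block=cell, statistic="mean")
    phase_cells = resilience.aggregate_to_coarse(truth.phase, block=cell, statistic="mean")
    landcover = (phase_cells > np.median(phase_cells)).astype(int)
    strata = synthetic.stratify_sites(rain_cells, green, landcover)
    plots = synthetic.sample_survey_plots(
        cover, strata, config.n_plots, config.survey_years, seed=config.seed, cell_size=cell
    )
    plots["pixel_id"] = plots["row"] * wc.grid_cols + plots["col"]
    merged = plots.merge(table, on=["pixel_id", "year"], how="inner")
    if len(merged) < len(plots):
        logger.warning("dropped %d plots without complete features", len(plots) - len(merged))

    train, holdout = bgi_model.split_holdout(merged, fraction=config.holdout_fraction, seed=config.seed)
    Xcols = features.PREDICTOR_COLUMNS
    std_train, stats_train = features.standardize(train, columns=Xcols)
    std_holdout = features.apply_standardization(holdout, stats_train)
    y_train = bgi_model.transform_response(100.0 * train["bare_fraction"].to_numpy())
    y_holdout = bgi_model.transform_response(100.0 * holdout["bare_fraction"].to_numpy())
    report = bgi_model.evaluate_candidates(
        std_train[Xcols].to_numpy(),
        y_train,
        std_holdout[Xcols].to_numpy(),
        y_holdout,
        repeats=config.cv_repeats,
        seed=config.seed,
    )
    chosen = bgi_model.select_model(report)

    # Final model: refit on every plot, restandardizing against all plots.
    std_all, stats_all = features.standardize(merged, columns=Xcols)
    y_all = bgi_model.transform_response(100.0 * merged["bare_fraction"].to_numpy())
    final = bgi_model.make_model(chosen, seed=config.seed)
    final.fit(std_all[Xcols].to_numpy(), y_all)
    state.update(
        {
            "plots": merged,
            "cv_report": report,
            "chosen_algorithm": chosen,
            "final_model": final,
            "standardization": stats_all,
        }
    )

    p = out / "plots.csv"
    plots[["row", "col", "year", "n_points", "bare_points", "stratum"]].to_csv(p, index=False)
    _record(manifest, "train", "plots", p)
    p = out / "cv_report.csv"
    report.drop(columns=["rmse_repeats", "r2_repeats"]).to_csv(p)
    _record(manifest, "train", "cv_report", p)
    p = write_json(
        out / "model_selection.json",
        {
            "chosen": chosen,
            "rule": "holdout RMSE, ties by holdout R2 then CV RMSE",
            "standardization": state["standardization"],
            "version": 1,
        },
    )
    _record(manifest, "train", "model_selection", p)


def _stage_predict(config: RunConfig, out: Path, state: dict, manifest: dict):
    table = _need(state, "feature_table", config, out, "features")
    model = _need(state, "final_model", config, out, "train")
    stats_all = _need(state, "standardization", config, out, "train")
    wc = config.world
    Xcols = features.PREDICTOR_COLUMNS
    std = features.apply_standardization(table, stats_all)
    n_pix = wc.grid_rows * wc.grid_cols
    features_by_year = {}
    for year, group in std.groupby("year"):
        X = np.full((n_pix, len(Xcols)), np.nan)
        X[group["pixel_id"].to_numpy()] = group[Xcols].to_numpy()
        features_by_year[int(year)] = X
    series = bgi_model.predict_series(model, features_by_year, wc.shape, reference_year=config.reference_year)
    state["bgi_series"] = series
    p = write_tiff(out / "bgi_normalized.tif", series.normalized)
    _record(manifest, "predict", "bgi_normalized", p)
    p = write_json(out / "bgi_years.json", {"years": series.years.tolist()})
    _record(manifest, "predict", "bgi_years", p)


def _stage_resilience(config: RunConfig, out: Path, state: dict, manifest: dict):
    series = _need(state, "bgi_series", config, out, "predict")
    coarse = resilience.aggregate_to_coarse(series.normalized, block=config.block)
    state["coarse_series"] = coarse
    results = resilience.analyze_resilience(
        series.years,
        coarse,
        k_shocks=config.k_shocks,
        final_years=config.final_years,
        seed=config.seed,
    )
    state["resilience"] = results
    p = write_tiff(out / "class_map.tif", results["class_map"].labels.astype(float))
    _record(manifest, "resilience", "class_map", p)
    p = out / "resilience_summary.csv"
    results["summary"].to_csv(p, index=False)
    _record(manifest, "resilience", "summary", p)
    v = dict(results["verdict"])
    v["shock_years"] = results["shocks"].years.tolist()
    p = write_json(out / "verdict.json", v)
    _record(manifest, "resilience", "verdict", p)


def _stage_trend(config: RunConfig, out: Path, state: dict, manifest: dict):
    series = _need(state, "bgi_series", config, out, "predict")
    truth = _need(state, "truth", config, out, "simulate")
    rainfall = _need(state, "rainfall", config, out, "simulate")
    coarse = state.get("coarse_series")
    if coarse is None:
        coarse = resilience.aggregate_to_coarse(series.normalized, block=config.block)
    wc = config.world
    annual = np.array([features.annual_rainfall(rainfall, int(y)).mean() for y in series.years])
    tmap = trend.pixelwise_rate(series.years, coarse, annual)

    block = config.block
    agg = lambda a: resilience.aggregate_to_coarse(a, block=block, statistic="mean")
    rain_mean = rainfall.annual_totals().mean(axis=0)
    prow, pcol = synthetic._cell_of_pixel(wc)
    rain_fine = rain_mean[prow[:, None], pcol[None, :]]
    desig_coarse = resilience.aggregate_to_coarse(truth.designation.astype(float), block=block)
    desig_names = np.asarray(synthetic.DESIGNATIONS)[np.round(desig_coarse).astype(int)]
    covariates = pd.DataFrame(
        {
            "human_density": agg(truth.human_density).ravel(),
            "rainfall": agg(rain_fine).ravel(),
            "livestock_density": agg(truth.livestock_density).ravel(),
            "designation": desig_names.ravel(),
        }
    )
    rr, cc = np.meshgrid(np.arange(tmap.rate.shape[0]), np.arange(tmap.rate.shape[1]), indexing="ij")
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    fit = trend.fit_spatial_model(tmap.rate.ravel(), covariates, coords, spatial=True)
    calib = trend.calibration_check(fit)
    state["trend_map"], state["spatial_fit"] = tmap, fit

    p = write_tiff(out / "trend_rate.tif", np.stack([tmap.rate, tmap.se]), band_names=["rate", "se"])
    _record(manifest, "trend", "trend_rate", p)
    p = out / "trend_coefficients.csv"
    fit.params.to_csv(p, index=False)
    _record(manifest, "trend", "coefficients", p)
    p = out / "calibration_pit.csv"
    calib["histogram"].to_csv(p, index=False)
    _record(manifest, "trend", "calibration", p)


# --- resumption loaders -----------------------------------------------------


def _load_feature_table(config, out):
    p = Path(out) / "features.parquet"
    if not p.exists():
        raise FileNotFoundError(p)
    return pd.read_parquet(p)


def _load_bgi_series(config, out):
    p = Path(out) / "bgi_normalized.tif"
    meta = Path(out) / "bgi_years.json"
    if not (p.exists() and meta.exists()):
        raise FileNotFoundError(p)
    norm = read_tiff(p)
    years = np.array(read_json(meta)["years"], dtype=int)
    return bgi_model.BareGroundSeries(years, raw=norm, scaled=norm, normalized=norm)


def _load_world_part(key):
    def loader(config, out):
        # The generator is deterministic under the config seed, so "loading"
        # simulate outputs is a cheap regeneration.
        world = synthetic.generate_world(config.world, config.scenario)
        return world[key]

    return loader


_LOADERS = {
    "feature_table": _load_feature_table,
    "bgi_series": _load_bgi_series,
    "truth": _load_world_part("truth"),
    "rainfall": _load_world_part("rainfall"),
    "cover": _load_world_part("cover"),
}

_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "features": _stage_features,
    "train": _stage_train,
    "predict": _stage_predict,
    "resilience": _stage_resilience,
    "trend": _stage_trend,
}
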