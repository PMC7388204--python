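"""End-to-end orchestration: simulate -> crosswalk -> vif -> stack -> fit ->
predict -> aggregate -> inequality -> counterfactual -> validate.

Each indicator (ORS, RHF, ORT) is modelled separately and each modelling
region fitted independently. All randomness funnels through named seeds
derived from the config seed; a manifest records stage order, output hashes,
and seeds, so a rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import aggregate_draws, compute_aroc, correlate_trends, count_untreated
from .counterfactual import run_counterfactual
from .crosswalk import apply_adjustment, fit_definition_adjustment
from .grid import RasterCube
from .inequality import country_inequality, inequality_trends
from .io import write_membership, write_observations, write_raster
from .mbg import HyperGrid, ModelSpec, draw_posterior_surfaces, fit_mbg, merge_draw_cubes
from .stacking import fit_child_learners, stack_design
from .synthworld import World, WorldConfig, simulate_world
from .validation import cross_validate
from .vif import vif_filter_by_region

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("ortmap.pipeline")

STAGES = (
    "simulate",
    "crosswalk",
    "vif",
    "stack",
    "fit",
    "predict",
    "aggregate",
    "inequality",
    "counterfactual",
    "validate",
)


@dataclass
class PipelineConfig:
    world: WorldConfig = field(default_factory=WorldConfig)
    indicators: tuple = ("ORS", "RHF", "ORT")
    n_draws: int = 250
    vif_threshold: float = 3.0
    # leaner default hyperparameter grid than fit_mbg's: the pipeline fits
    # six indicator-region models plus the CV refits, and a 27-point grid
    # keeps the whole chain at desk scale
    hyper: HyperGrid = field(
        default_factory=lambda: HyperGrid(
            sigma2_sp=(0.25, 1.0, 2.0),
            range_sp=(3.0, 6.0, 12.0),
            rho_t=(0.4, 0.7, 0.9),
            tau2=(0.02,),
        )
    )
    cv_folds: int = 5
    cv_draws: int = 100
    seed: int = 0

    def __post_init__(self):
        bad = set(self.indicators) - {"ORS", "RHF", "ORT"}
        if bad:
            raise ValueError(f"unknown indicators {sorted(bad)}")


@dataclass
class PipelineResult:
    manifest: dict
    world: World
    aggregates: dict  # indicator -> level -> AdminAggregate
    cubes: dict  # indicator -> PosteriorDrawCube
    inequality: dict
    counterfactual: dict
    cv: object
    recovery: dict  # indicator -> admin2 truth-recovery diagnostics


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record_region(obs: pd.DataFrame, grid) -> np.ndarray:
    out = np.empty(len(obs), dtype=int)
    for i, rec in enumerate(obs.itertuples(index=False)):
        if rec.geo_type == "point":
            out[i] = grid.region_of_cell[rec.cell_id]
        else:
            cells = grid.cells_of("admin1", rec.polygon_id)
            out[i] = grid.region_of_cell[cells[0]]
    return out


def _truth_admin2(world: World, indicator: str) -> pd.DataFrame:
    """Population-weighted truth aggregate per admin2-year (recovery oracle)."""
    grid = world.grid
    p = world.truths[indicator].values[0]
    pop = world.population.layer("population")
    rows = {}
    for u in grid.units("admin2"):
        cells = grid.cells_of("admin2", u)
        w = pop[:, cells]
        rows[int(u)] = (p[:, cells] * w).sum(axis=1) / w.sum(axis=1)
    return pd.DataFrame(rows, index=list(grid.years)).T


def run_pipeline(config: PipelineConfig | None = None, outdir=None) -> PipelineResult:
    """Run the full chain and write artifacts plus a manifest to ``outdir``."""
    config = config or PipelineConfig()
    outdir = Path(outdir) if outdir is not None else Path("ortmap_run")
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(config.seed)
    seeds = {
        name: int(root.integers(2**31))
        for name in ("world", "stack", "draws", "cv")
    }
    manifest = {"config_seed": config.seed, "seeds": seeds, "stages": []}
    t_start = time.time()

    def finish_stage(name, outputs=(), **extra):
        entry = {
            "stage": name,
            "elapsed_s": round(time.time() - finish_stage.t0, 3),
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
        }
        entry.update(extra)
        manifest["stages"].append(entry)
        log.info("stage %-14s done in %.1fs", name, entry["elapsed_s"])
        finish_stage.t0 = time.time()

    finish_stage.t0 = t_start

    try:
        # -- simulate ------------------------------------------------------
        world = simulate_world(config.world, seeds["world"])
        for ind in ("ORS", "RHF"):
            if "ORT" in world.truths and ind in world.truths:
                assert np.all(
                    world.truths["ORT"].values >= world.truths[ind].values - 1e-12
                ), "ORT coverage must dominate its components"
        obs_path = outdir / "observations.csv"
        write_observations(obs_path, world.observations)
        mem_path = outdir / "membership.csv"
        write_membership(mem_path, world.grid)
        cov_path = outdir / "covariates.tif"
        write_raster(cov_path, world.covariates)
        finish_stage("simulate", [obs_path, mem_path, cov_path, cov_path.with_suffix(".tif.json")])

        # -- crosswalk -----------------------------------------------------
        obs = world.observations
        has_nonstd = (
            (obs["indicator"] == "RHF") & (obs["definition"] == "nonstandard")
        ).any()
        if "RHF" in config.indicators and has_nonstd:
            model = fit_definition_adjustment(obs, "RHF")
            obs = apply_adjustment(obs, model)
            xwalk_report = {
                "intercept": model.intercept,
                "slope": model.slope,
                "n_calibration": model.n_calibration,
            }
        else:
            xwalk_report = {"skipped": True}
        adj_path = outdir / "observations_adjusted.csv"
        write_observations(adj_path, obs)
        (outdir / "crosswalk.json").write_text(json.dumps(xwalk_report))
        finish_stage("crosswalk", [adj_path, outdir / "crosswalk.json"], report=xwalk_report)

        # -- vif -----------------------------------------------------------
        vif_reports = vif_filter_by_region(world.covariates, config.vif_threshold)
        vif_json = {
            str(r): {"retained": rep.retained, "removed": rep.removed, "vif": rep.vif}
            for r, rep in vif_reports.items()
        }
        (outdir / "vif.json").write_text(json.dumps(vif_json))
        finish_stage("vif", [outdir / "vif.json"])

        # -- stack / fit / predict per indicator x region ------------------
        grid = world.grid
        regions = grid.units("region")
        region_of_rec = {ind: None for ind in config.indicators}
        bundles, fits, cubes = {}, {}, {}
        stack_elapsed = fit_elapsed = predict_elapsed = 0.0
        for ind in config.indicators:
            obs_ind = obs[obs["indicator"] == ind].reset_index(drop=True)
            rr = _record_region(obs_ind, grid)
            region_of_rec[ind] = rr
            region_cubes = []
            for rg in regions:
                obs_r = obs_ind[rr == rg].reset_index(drop=True)
                retained = vif_reports[int(rg)].retained
                idx = [world.covariates.layers.index(nm) for nm in retained]
                covs_r = RasterCube(
                    world.covariates.values[idx], retained, grid
                )
                t0 = time.time()
                bundle = fit_child_learners(
                    obs_r, covs_r, seed=seeds["stack"] + 13 * int(rg)
                )
                design = stack_design(bundle)
                stack_elapsed += time.time() - t0
                bundles[(ind, int(rg))] = bundle
                t0 = time.time()
                fit = fit_mbg(
                    obs_r,
                    grid,
                    pop=world.population,
                    design=design,
                    spec=ModelSpec(region=int(rg), hyper=config.hyper),
                )
                fit_elapsed += time.time() - t0
                fits[(ind, int(rg))] = fit
                t0 = time.time()
                region_cubes.append(
                    draw_posterior_surfaces(
                        fit, config.n_draws, seed=seeds["draws"] + 7 * int(rg)
                    )
                )
                predict_elapsed += time.time() - t0
            cubes[ind] = merge_draw_cubes(region_cubes)
        oof_path = outdir / "stacker_oof.csv"
        pd.concat(
            [
                pd.DataFrame(b.oof, columns=b.learners).assign(indicator=ind, region=rg)
                for (ind, rg), b in bundles.items()
            ],
            ignore_index=True,
        ).to_csv(oof_path, index=False)
        finish_stage("stack", [oof_path], elapsed_stack_s=round(stack_elapsed, 3))
        hyper_path = outdir / "hyper_posterior.csv"
        pd.concat(
            [f.hyper_posterior().assign(indicator=ind, region=rg) for (ind, rg), f in fits.items()],
            ignore_index=True,
        ).to_csv(hyper_path, index=False)
        finish_stage("fit", [hyper_path], elapsed_fit_s=round(fit_elapsed, 3))
        mean_paths = []
        for ind, cube in cubes.items():
            mean_cube = RasterCube(
                cube.full_surface().mean(axis=0)[None], [f"p_{ind}_mean"], grid
            )
            p = outdir / f"posterior_mean_{ind}.tif"
            write_raster(p, mean_cube)
            mean_paths += [p, p.with_suffix(".tif.json")]
        finish_stage("predict", mean_paths, elapsed_predict_s=round(predict_elapsed, 3))

        # -- aggregate -----------------------------------------------------
        aggregates = {}
        agg_paths = []
        for ind, cube in cubes.items():
            aggregates[ind] = {
                level: aggregate_draws(cube, world.population, level)
                for level in ("country", "admin1", "admin2")
            }
            p = outdir / f"aggregate_{ind}_admin2.csv"
            aggregates[ind]["admin2"].summary().to_csv(p, index=False)
            agg_paths.append(p)
        y0, y1 = grid.years[0], grid.years[-1]
        aroc = {
            ind: compute_aroc(aggregates[ind]["admin2"], y0, y1).summary()
            for ind in config.indicators
        }
        for ind, df in aroc.items():
            p = outdir / f"aroc_{ind}_admin2.csv"
            df.to_csv(p, index=False)
            agg_paths.append(p)
        untreated = {}
        for ind in config.indicators:
            untreated[ind] = count_untreated(cubes[ind], world.population, "admin2")
        trends = None
        if {"ORS", "RHF"} <= set(config.indicators):
            trends = correlate_trends(
                aggregates["ORS"]["admin2"].mean_series(),
                aggregates["RHF"]["admin2"].mean_series(),
            )
            (outdir / "trend_correlation.json").write_text(
                json.dumps(
                    {k: v for k, v in trends.items() if k != "per_unit"}
                )
            )
            agg_paths.append(outdir / "trend_correlation.json")
        finish_stage("aggregate", agg_paths)

        # -- inequality ----------------------------------------------------
        ineq_ind = "ORS" if "ORS" in config.indicators else config.indicators[0]
        ineq0 = country_inequality(aggregates[ineq_ind]["admin2"], grid, y0)
        ineq1 = country_inequality(aggregates[ineq_ind]["admin2"], grid, y1)
        ineq_trends = inequality_trends(ineq0, ineq1)
        p = outdir / "inequality.csv"
        pd.concat([ineq0, ineq1], ignore_index=True).to_csv(p, index=False)
        (outdir / "inequality_trends.json").write_text(json.dumps(ineq_trends["summary"]))
        finish_stage("inequality", [p, outdir / "inequality_trends.json"])

        # -- counterfactual ------------------------------------------------
        cf = None
        cf_paths = []
        if "ORS" in config.indicators:
            t1 = grid.n_years - 1
            deaths = world.mortality.layer("deaths")[t1]
            pop_cells = world.population.layer("population")[t1]
            a2 = grid.admin2_of_cell
            deaths_by_unit = pd.Series(
                {int(u): float(deaths[a2 == u].sum()) for u in grid.units("admin2")}
            )
            pop_by_unit = pd.Series(
                {int(u): float(pop_cells[a2 == u].sum()) for u in grid.units("admin2")}
            )
            cf = run_counterfactual(
                deaths_by_unit, aggregates["ORS"]["admin2"], pop_by_unit, y0, y1
            )
            for name, table in cf.items():
                p = outdir / f"counterfactual_{name}.csv"
                table.to_csv(p, index=False)
                cf_paths.append(p)
        finish_stage("counterfactual", cf_paths)

        # -- validate ------------------------------------------------------
        cv_ind = "ORS" if "ORS" in config.indicators else config.indicators[0]
        obs_cv = obs[obs["indicator"] == cv_ind].reset_index(drop=True)
        cv = cross_validate(
            obs_cv,
            grid,
            world.population,
            spec=ModelSpec(hyper=config.hyper),
            k=config.cv_folds,
            seed=seeds["cv"],
            n_draws=config.cv_draws,
        )
        p = outdir / "cv_report.json"
        p.write_text(json.dumps({"pooled": cv.pooled, "per_fold": cv.per_fold.to_dict("records")}))
        finish_stage("validate", [p])
    except Exception as exc:
        manifest["error"] = {"stage": STAGES[len(manifest["stages"])], "message": str(exc)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    # truth-recovery diagnostics (synthetic worlds carry their truth)
    recovery = {}
    for ind in config.indicators:
        truth = _truth_admin2(world, ind)
        est = aggregates[ind]["admin2"]
        summ = est.summary()
        truth_vals = np.array(
            [truth.loc[r.unit_id, r.year] for r in summ.itertuples(index=False)]
        )
        r = float(np.corrcoef(truth_vals, summ["mean"])[0, 1])
        inside = float(
            np.mean((truth_vals >= summ["lower95"]) & (truth_vals <= summ["upper95"]))
        )
        recovery[ind] = {"pearson_r": r, "ui_coverage": inside}
    manifest["recovery"] = recovery
    manifest["total_elapsed_s"] = round(time.time() - t_start, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PipelineResult(
        manifest=manifest,
        world=world,
        aggregates=aggregates,
        cubes=cubes,
        inequality={"y0": ineq0, "y1": ineq1, "trends": ineq_trends},
        counterfactual=cf,
        cv=cv,
        recovery=recovery,
    )
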