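"""End-to-end pipeline: simulate → standardize → upscale → invert → attribute.

Chains the stages in derivation order and writes all artifacts plus a
machine-readable JSON report of every headline statistic.  Idempotent under
a fixed master seed: rerunning produces byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import traceback
import warnings
from pathlib import Path
from typing import Any, Dict, Optional

import numpy as np
import pandas as pd
import xarray as xr

from . import attribution as attrib
from . import core, model_zoo, synthetic, thermal, upscale
from .config import RunConfig
from .constants import PhysioConstants
from .grids import CovariateGrid

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def run_pipeline(
    config: Optional[RunConfig] = None, output_dir: Optional[str] = None
) -> Dict[str, Any]:
    """Run every enabled stage; return (and write) the run report.

    Any stage failure marks that stage failed in the report and skips the
    stages depending on it.
    """
    cfg = config or RunConfig()
    outdir = Path(output_dir or cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: Dict[str, Any] = {"seed": cfg.seed, "stages": {}}
    state: Dict[str, Any] = {}

    def run_stage(name, fn, requires=()):
        for dep in requires:
            if report["stages"].get(dep) != "ok":
                report["stages"][name] = f"skipped (requires {dep})"
                return
        try:
            fn()
            report["stages"][name] = "ok"
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("stage %s failed:\n%s", name, traceback.format_exc())
            report["stages"][name] = f"failed: {exc}"

    constants = PhysioConstants(**cfg["constants"])

    def stage_simulate():
        gcfg = cfg["grid"]
        grid = synthetic.make_covariate_grid(
            shape=tuple(gcfg["shape"]),
            seed=cfg.stage_seed("grid"),
            smoothness=gcfg["smoothness"],
            mask_fraction=gcfg["mask_fraction"],
            within_group_correlation=gcfg["within_group_correlation"],
        )
        traits = synthetic.make_traits(
            grid, seed=cfg.stage_seed("traits"), rel_sd=cfg["traits"]["rel_sd"]
        )
        tcfg = cfg["truth"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # flooring count goes in report
            truth = synthetic.make_truth(
                grid,
                traits,
                coefficients=tcfg["coefficients"],
                intercept=tcfg["intercept"],
                pft_offsets=tcfg["pft_offsets"],
                noise_sd=tcfg["noise_sd"],
                constants=constants,
                seed=cfg.stage_seed("truth"),
                floor_pct=tcfg["floor_pct"],
            )
        ocfg = cfg["observations"]
        obs = synthetic.sample_observations(
            truth,
            grid,
            n=ocfg["n"],
            n_clusters=ocfg["n_clusters"],
            cluster_radius=ocfg["cluster_radius"],
            obs_noise_sd=ocfg["obs_noise_sd"],
            tleaf_range=tuple(ocfg["tleaf_range"]),
            isolated_fraction=ocfg["isolated_fraction"],
            constants=constants,
            seed=cfg.stage_seed("observations"),
        )
        grid.to_netcdf(outdir / "covariates.nc")
        traits.to_netcdf(outdir / "traits.nc")
        truth_ds = xr.Dataset(
            {
                "flnr_true": (("lat", "lon"), truth.flnr_true),
                "vcmax25_true": (("lat", "lon"), truth.vcmax25_true),
            },
            coords={"lat": grid.lat, "lon": grid.lon},
        )
        truth_ds.to_netcdf(outdir / "truth.nc", engine="scipy")
        synthetic.write_observations(obs, outdir / "observations.csv")
        state.update(grid=grid, traits=traits, truth=truth, obs=obs)
        report["simulate"] = {
            "n_vegetated_cells": grid.n_vegetated,
            "n_observations": len(obs),
            "n_floored_cells": truth.n_floored,
            "flnr_true_mean": float(np.nanmean(truth.flnr_true)),
            "flnr_true_sd": float(np.nanstd(truth.flnr_true)),
        }

    def stage_standardize():
        obs = state["obs"].copy()
        obs["vcmax25"] = thermal.standardize_to_25(
            obs["vcmax_obs"].to_numpy(), obs["tleaf"].to_numpy(), constants
        )
        synthetic.write_observations(obs, outdir / "observations.csv")
        state["obs"] = obs
        report["standardize"] = {
            "vcmax25_obs_mean": float(obs["vcmax25"].mean()),
            "vcmax25_obs_sd": float(obs["vcmax25"].std()),
        }

    def stage_rf():
        rcfg = cfg["rf"]
        candidates = rcfg["candidates"] or (
            list(state["grid"].layers) + ["pft"]
        )
        model = upscale.VcmaxForest(
            state["obs"],
            candidates,
            response="vcmax25",
            n_trees=rcfg["n_trees"],
            seed=cfg.stage_seed("rf"),
            min_rows=rcfg["min_rows"],
        )
        ranking = model.rank_importance()
        selected, trace = model.select_predictors(ranking)
        results = model.fit(selected)
        cv = {}
        for mode in ("conventional", "spatial"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cv[mode] = model.cross_validate(
                        selected,
                        mode=mode,
                        holdout_fraction=rcfg["holdout_fraction"],
                        exclusion_radius_km=rcfg["exclusion_radius_km"],
                        n_reps=rcfg["n_reps"],
                        seed=cfg.stage_seed("rf") + 1,
                    ).to_dict()
                except RuntimeError as exc:
                    # a dense site network on a small domain can leave no
                    # validation rows outside the exclusion radius
                    cv[mode] = {"error": str(exc)}
        vcmax_map = results.predict_grid(state["grid"])
        vcmax_map.to_netcdf(outdir / "vcmax25_rf.nc")
        state.update(rf_results=results, vcmax_map=vcmax_map)
        report["rf"] = {
            "importance_ranking": ranking,
            "selected_predictors": selected,
            "oob_trace": trace,
            "oob_r2": results.oob_r2,
            "oob_mse": results.oob_mse,
            "cross_validation": cv,
            "vcmax25_grid_mean": float(np.nanmean(vcmax_map.mean)),
            "vcmax25_grid_sd": float(np.nanstd(vcmax_map.mean)),
        }

    def stage_invert():
        product = core.bootstrap_flnr(
            state["vcmax_map"],
            state["traits"],
            constants=constants,
            n_boot=cfg["bootstrap"]["n_boot"],
            seed=cfg.stage_seed("bootstrap"),
            mode="per_source",
        )
        flnr = product.flnr
        flnr.to_netcdf(outdir / "flnr.nc")
        src_ds = xr.Dataset(
            {
                f"flnr_sd_source_{k}": (("lat", "lon"), v)
                for k, v in product.source_contributions.items()
            },
            coords={"lat": flnr.lat, "lon": flnr.lon},
        )
        src_ds.to_netcdf(outdir / "flnr_uncertainty_sources.nc", engine="scipy")
        state["flnr_product"] = product
        report["flnr"] = {
            "global_mean": float(np.nanmean(flnr.mean)),
            "global_spatial_sd": float(np.nanstd(flnr.mean)),
            "mean_total_uncertainty": float(np.nanmean(flnr.sd)),
            "source_mean_sd": {
                k: float(np.nanmean(v))
                for k, v in product.source_contributions.items()
            },
            "n_boot": product.n_boot,
        }

    def stage_attribution():
        acfg = cfg["attribution"]
        grid: CovariateGrid = state["grid"]
        table = grid.table()
        flnr_vals = state["flnr_product"].flnr.mean[grid.mask]
        ok = np.isfinite(flnr_vals)
        table = table.loc[ok].reset_index(drop=True)
        flnr_vals = flnr_vals[ok]
        pca = attrib.group_pca(table)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gam = attrib.FLNRAttribution(
                flnr_vals,
                pca,
                table["pft"].to_numpy(),
                n_pcs=acfg["n_pcs"],
                spline_df=acfg["spline_df"],
                alpha=acfg["alpha"],
                min_pft_cells=acfg["min_pft_cells"],
            ).fit()
            ge = gam.compute_group_effects(acfg["thresholds"])
            sens = gam.fit_sensitivities(table, scope="global")
            sens_pft = gam.fit_sensitivities(
                table, scope="per_pft", min_cells=acfg["per_pft_min_cells"]
            )
        direct = attrib.direct_sensitivity_fit(
            table.assign(flnr=flnr_vals), response="flnr"
        )
        gam.partial_curves().to_csv(outdir / "partial_curves.csv", index=False)
        pd.concat([sens.table, sens_pft.table]).to_csv(
            outdir / "sensitivities.csv", index=False
        )
        direct.to_csv(outdir / "sensitivities_direct.csv")
        effect_fields = {}
        for g, eff in ge.effects.items():
            vals = np.full(ok.size, np.nan)
            vals[ok] = eff
            effect_fields[f"effect_{g}"] = (("lat", "lon"), grid.field_from_values(vals))
        effect_ds = xr.Dataset(
            effect_fields, coords={"lat": grid.lat, "lon": grid.lon}
        )
        effect_ds.to_netcdf(outdir / "group_effects.nc", engine="scipy")
        report["attribution"] = {
            "gam_r2": gam.r_squared(),
            "explained_variance_top3": {
                g: float(np.sum(pca.explained[g][:3]))
                for g in pca.explained
            },
            "area_fractions": ge.area_fractions,
            "mean_abs_effects": {
                g: {"mean": m, "sd": s}
                for g, (m, s) in ge.mean_abs_effects.items()
            },
            "sensitivities_global": sens.table.to_dict("records"),
            "intercept_global": sens.intercepts.get("global"),
            "equation_global": sens.equation_string("global"),
            "sensitivities_direct": direct.table.to_dict("records"),
            "intercept_direct": direct.intercepts.get("global"),
            "equation_direct": direct.equation_string("global"),
        }

    def stage_zoo():
        grid: CovariateGrid = state["grid"]
        flnr_ref = state["flnr_product"].flnr.mean
        lnc = state["traits"].lnc_mean()
        specs = {"EM3": model_zoo.EmpiricalModelSpec.em3(),
                 "EM4": model_zoo.EmpiricalModelSpec.em4()}
        example = model_zoo.load_example_specs()
        specs.update(example)
        zoo_report = {}
        for model_id in cfg["zoo"]["models"]:
            spec = specs.get(model_id)
            if spec is None:
                zoo_report[model_id] = "unknown model id"
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v = model_zoo.evaluate_model(spec, grid)
                fl = model_zoo.implied_flnr(v, lnc, constants)
                comp = model_zoo.compare_maps(flnr_ref, fl, grid.pft)
            zoo_report[model_id] = {
                "flnr_mean": float(np.nanmean(fl)),
                "flnr_sd": float(np.nanstd(fl)),
                "comparison": comp.to_dict(),
            }
        report["zoo"] = zoo_report

    run_stage("simulate", stage_simulate)
    run_stage("standardize", stage_standardize, requires=("simulate",))
    run_stage("rf", stage_rf, requires=("standardize",))
    run_stage("invert", stage_invert, requires=("rf",))
    if cfg["attribution"]["enabled"]:
        run_stage("attribution", stage_attribution, requires=("invert",))
    if cfg["zoo"]["enabled"]:
        run_stage("zoo", stage_zoo, requires=("invert",))

    report_clean = _jsonable(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report_clean, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report_clean
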