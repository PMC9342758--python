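"""End-to-end orchestration of the synthetic study and analysis pipeline.

Stage order: landscape -> covariates -> telemetry -> ranges -> design (both
scales plus the ratio diagnostic) -> tune/fit -> importance/PDP/interactions
-> leave-one-individual-out CV -> projection.  Every artifact is written as a
text file and recorded in a manifest with SHA-256 checksums; a second run
with the same config reproduces identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .. import io as hio
from ..covariates import EvennessParams, build_stack
from ..design import RATIO_LADDER, build_table, ratio_stabilization
from ..forest_model import (
    ForestConfig,
    fit_forest,
    permutation_importance,
    tune,
)
from ..interpret import partial_dependence, project_map, rank_interactions
from ..landscape_sim import LandscapeConfig, generate_landscape, generate_roads
from ..ranges import kde_home_range, radius_from_area, study_area
from ..telemetry_sim import (
    ErrorModel,
    TrueRSF,
    simulate_individuals,
    simulate_telemetry,
)
from ..validate import loio_cv
from .config import PipelineConfig, stage_seed

__all__ = ["StageError", "run_pipeline"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _rsf_from_config(section: dict) -> TrueRSF:
    interactions = {
        tuple(k.split("*")): v
        for k, v in (section.get("interactions") or {}).items()
    }
    return TrueRSF(
        coefficients=dict(section.get("coefficients") or {}),
        interactions=interactions,
        rules=list(section.get("rules") or []),
        intercept=float(section.get("intercept", 0.0)),
        sex_offsets=dict(section.get("sex_offsets") or {}),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write artifacts, and return the manifest dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"base_seed": config.base_seed, "stages": {}, "files": {}}
    stage = "init"

    def finish_stage(name: str, t0: float, *files: Path) -> None:
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 3)}
        for f in files:
            manifest["files"][str(f.relative_to(outdir))] = _sha256(f)
        log.info("stage %-12s done in %.2fs", name, time.time() - t0)

    try:
        # -- landscape -----------------------------------------------------
        stage = "landscape"
        t0 = time.time()
        lc_kwargs = dict(config.landscape)
        lc_kwargs.setdefault("seed", stage_seed(config.base_seed, "landscape"))
        lconf = LandscapeConfig(**lc_kwargs)
        class_map = generate_landscape(lconf)
        roads = generate_roads(lconf, seed=stage_seed(config.base_seed, "roads"))
        f_map = outdir / "landscape.asc"
        f_roads = outdir / "roads.geojson"
        hio.write_class_map(f_map, class_map)
        hio.write_roads(f_roads, roads)
        finish_stage(stage, t0, f_map, Path(str(f_map) + ".legend.json"), f_roads)

        # -- covariates ----------------------------------------------------
        stage = "covariates"
        t0 = time.time()
        window = float(config.telemetry.get("evenness_window_radius", 500.0))
        stack = build_stack(class_map, roads, EvennessParams(window_radius=window))
        stack_dir = outdir / "covariates"
        hio.write_stack(stack_dir, stack)
        finish_stage(stage, t0, *sorted(stack_dir.glob("*")))

        # -- telemetry -----------------------------------------------------
        stage = "telemetry"
        t0 = time.time()
        tcfg = config.telemetry
        rsf = _rsf_from_config(config.rsf)
        individuals = simulate_individuals(
            n=int(tcfg.get("n_individuals", 27)),
            sex_split=tuple(tcfg.get("sex_split", (14, 13))),
            class_map=class_map,
            mean_hr_area=float(tcfg.get("mean_hr_area", 135.0e6)),
            seed=stage_seed(config.base_seed, "individuals"),
            n_points_mean=float(tcfg.get("n_points_mean", 258.0)),
            n_points_sd=float(tcfg.get("n_points_sd", 36.0)),
            availability_radius=tcfg.get("availability_radius"),
        )
        err = ErrorModel(sd=float(tcfg.get("location_error", 94.0)))
        telemetry = simulate_telemetry(
            individuals, stack, rsf, err,
            seed=stage_seed(config.base_seed, "telemetry"),
        )
        f_tel = outdir / "telemetry.csv"
        telemetry.to_csv(f_tel, index=False)
        f_rsf = outdir / "true_rsf.yaml"
        f_rsf.write_text(yaml.safe_dump({
            "coefficients": rsf.coefficients,
            "interactions": {f"{a}*{b}": v for (a, b), v in rsf.interactions.items()},
            "rules": rsf.rules,
            "intercept": rsf.intercept,
            "sex_offsets": rsf.sex_offsets,
        }))
        finish_stage(stage, t0, f_tel, f_rsf)

        # -- ranges --------------------------------------------------------
        stage = "ranges"
        t0 = time.time()
        buffer_radius = float(config.ranges.get(
            "buffer_radius",
            radius_from_area(float(tcfg.get("mean_hr_area", 135.0e6))),
        ))
        sa = study_area(telemetry[["x", "y"]].to_numpy(), buffer_radius)
        f_sa = outdir / "study_area.geojson"
        hio.write_polygons(f_sa, sa.polygons, {"buffer_radius": buffer_radius})
        hr_grid = int(config.ranges.get("kde_grid_size", 120))
        homeranges = {}
        hr_meta = {}
        for ind in individuals:
            pts = telemetry.loc[telemetry["id"] == ind.id, ["x", "y"]].to_numpy()
            hr = kde_home_range(pts, iso_level=0.95, individual_id=ind.id,
                                grid_size=hr_grid)
            homeranges[ind.id] = hr.polygons
            hr_meta[ind.id] = {
                "bandwidth": np.asarray(hr.bandwidth).tolist(),
                "mass_enclosed": hr.mass_enclosed,
                "area_m2": hr.area,
            }
        f_hr = outdir / "home_ranges.geojson"
        features = [
            {"type": "Feature",
             "geometry": hio.mapping(geom),
             "properties": {"id": ind_id}}
            for ind_id, geom in homeranges.items()
        ]
        f_hr.write_text(json.dumps({"type": "FeatureCollection",
                                    "features": features}))
        f_hrm = outdir / "home_ranges.json"
        f_hrm.write_text(json.dumps(hr_meta, indent=1))
        finish_stage(stage, t0, f_sa, f_hr, f_hrm)

        # -- design --------------------------------------------------------
        stage = "design"
        t0 = time.time()
        dcfg = config.design
        ratio_tables = {}
        for r in RATIO_LADDER:
            ratio_tables[r] = build_table(
                telemetry, stack, sa.polygons, ratio=r, scale="study_area",
                seed=stage_seed(config.base_seed, f"design-ratio-{r}"),
            )
        diag = ratio_stabilization(
            ratio_tables, epsilon=float(dcfg.get("epsilon", 0.05))
        )
        f_diag = outdir / "ratio_diagnostic.csv"
        diag.stats.to_csv(f_diag, index=False)
        f_diag_json = outdir / "ratio_diagnostic.json"
        f_diag_json.write_text(json.dumps({
            "selected_ratio": diag.selected_ratio,
            "epsilon": diag.epsilon,
            "stabilized": diag.stabilized,
        }, indent=1))
        ratio = int(dcfg.get("ratio", diag.selected_ratio))
        if ratio in ratio_tables:
            table_sa = ratio_tables[ratio]
        else:
            table_sa = build_table(
                telemetry, stack, sa.polygons, ratio=ratio, scale="study_area",
                seed=stage_seed(config.base_seed, f"design-ratio-{ratio}"),
            )
        table_hr = build_table(
            telemetry, stack, homeranges, ratio=ratio, scale="home_range",
            seed=stage_seed(config.base_seed, "design-hr"),
        )
        f_tab_sa = outdir / "table_study_area.csv"
        f_tab_hr = outdir / "table_home_range.csv"
        table_sa.to_csv(f_tab_sa, index=False)
        table_hr.to_csv(f_tab_hr, index=False)
        finish_stage(stage, t0, f_diag, f_diag_json, f_tab_sa, f_tab_hr)

        # -- fit -----------------------------------------------------------
        stage = "fit"
        t0 = time.time()
        fcfg = config.forest
        seed = stage_seed(config.base_seed, "forest")
        grid = [
            ForestConfig(
                n_trees=int(g.get("n_trees", 200)),
                mtry=int(g.get("mtry", 6)),
                sample_fraction=float(g.get("sample_fraction", 0.623)),
                min_node=int(g.get("min_node", 5)),
                seed=seed,
            )
            for g in fcfg.get("grid", [{}])
        ]
        tuning = tune(table_sa, grid)
        fitted = fit_forest(table_sa, tuning.chosen)
        f_tune = outdir / "tuning.json"
        f_tune.write_text(json.dumps({
            "chosen": vars(tuning.chosen).copy(),
            "grid_oob": [
                {**vars(cfg), "oob_error": oob}
                for cfg, oob in zip(tuning.grid, tuning.oob_per_config)
            ],
            "oob_error": fitted.oob_error,
        }, indent=1, default=float))
        finish_stage(stage, t0, f_tune)

        # -- interpret -----------------------------------------------------
        stage = "interpret"
        t0 = time.time()
        icfg = config.interpret
        imp = permutation_importance(
            fitted, table_sa,
            n_reps=int(icfg.get("importance_reps", 3)),
            seed=stage_seed(config.base_seed, "importance"),
        )
        f_imp = outdir / "importance.csv"
        imp.to_csv(f_imp, index=False)
        n_grid = int(icfg.get("pdp_grid", 20))
        pdp_frames = []
        for pred in fitted.feature_names:
            if pred == "sex":
                continue
            curve = partial_dependence(fitted, table_sa, pred, n_grid=n_grid)
            pdp_frames.append(pd.DataFrame({
                "predictor": pred, "grid": curve.grid,
                "dependence": curve.dependence,
            }))
        f_pdp = outdir / "pdp.csv"
        pd.concat(pdp_frames, ignore_index=True).to_csv(f_pdp, index=False)
        ranking = rank_interactions(fitted, table_sa,
                                    n_bins=int(icfg.get("n_bins", 10)))
        f_int = outdir / "interactions.csv"
        ranking.table.to_csv(f_int, index=False)
        finish_stage(stage, t0, f_imp, f_pdp, f_int)

        # -- crossval ------------------------------------------------------
        stage = "crossval"
        t0 = time.time()
        vcfg = config.validation
        cv_cfg = ForestConfig(
            n_trees=int(vcfg.get("n_trees", tuning.chosen.n_trees)),
            mtry=tuning.chosen.mtry,
            sample_fraction=tuning.chosen.sample_fraction,
            min_node=tuning.chosen.min_node,
            seed=stage_seed(config.base_seed, "crossval"),
        )
        cv = loio_cv(table_sa, cv_cfg, scale="study_area")
        f_cv = outdir / "cv_study_area.csv"
        cv.per_individual.to_csv(f_cv, index=False)
        f_cvs = outdir / "cv_summary.json"
        f_cvs.write_text(json.dumps({
            "study_area": {"mean_auc": cv.mean_auc, "se_auc": cv.se_auc,
                           "n_skipped": cv.n_skipped},
        }, indent=1))
        finish_stage(stage, t0, f_cv, f_cvs)

        # -- project -------------------------------------------------------
        stage = "project"
        t0 = time.time()
        raster = project_map(fitted, stack)
        f_pred = outdir / "prediction.asc"
        hio.write_ascii_grid(f_pred, raster.values, raster.cell_size,
                             raster.origin)
        finish_stage(stage, t0, f_pred)
    except Exception as exc:  # persist what we have, then re-raise
        f_manifest = outdir / "manifest.json"
        f_manifest.write_text(json.dumps(manifest, indent=1))
        raise StageError(stage, exc) from exc

    f_manifest = outdir / "manifest.json"
    f_manifest.write_text(json.dumps(manifest, indent=1))
    return manifest
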