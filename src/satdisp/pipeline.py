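"""End-to-end orchestration: synth/ingest -> tune -> filter -> screen ->
dynamics -> estimate -> imagery diagnostics.

Every stage writes its tables under the run directory and contributes
record counts to a JSON manifest, so the post-processing funnel (images
in, images surviving screening, cities retained for estimation) is
auditable.  No stage drops records silently: each removal lands in
exactly one stage's ledger.  A run is deterministic given the world
config and run config (all randomness flows from their seeds); the
manifest contains no timestamps so reruns hash identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import box

from . import car_dynamics, detection_processing as dp, idp_estimation as idp
from . import image_screening as scr
from .config import RunConfig, WorldConfig, save_config, _to_plain
from .errors import FitError, StageError
from .geo import read_geojson, sha256_file
from .imagery_diagnostics import fit_feature_glm, glm_diagnostics
from .synthetic_world import World, generate_world


@dataclass
class PipelineInputs:
    """The file contract, in memory: what every run consumes."""

    aois: dict
    oblast_of: dict
    fine_cells: pd.DataFrame
    exclusions: dp.ExclusionLayer
    images: pd.DataFrame
    detections: pd.DataFrame
    truth_points: pd.DataFrame | None = None

    @classmethod
    def from_world(cls, world: World) -> "PipelineInputs":
        return cls(
            aois=world.aois,
            oblast_of=world.oblast_of,
            fine_cells=world.fine_cells,
            exclusions=world.exclusions,
            images=world.images,
            detections=world.detections,
            truth_points=world.truth.truth_points,
        )

    @classmethod
    def from_dir(cls, indir: str | Path) -> "PipelineInputs":
        indir = Path(indir)
        aoi_feats = read_geojson(indir / "aois.geojson")
        aois = {p["aoi_id"]: g for g, p in aoi_feats}
        oblast_of = {p["aoi_id"]: p.get("oblast", p["aoi_id"]) for _, p in aoi_feats}
        exclusions = dp.ExclusionLayer.from_geojson(indir / "exclusions.geojson")
        images = pd.read_csv(indir / "images.csv")
        images["acquired_at"] = pd.to_datetime(images["acquired_at"], utc=True)
        detections = pd.read_csv(indir / "detections.csv")
        detections.insert(0, "det_id", np.arange(len(detections), dtype=np.int64))
        tp_path = indir / "truth_points.csv"
        truth_points = pd.read_csv(tp_path) if tp_path.exists() else None
        return cls(
            aois=aois, oblast_of=oblast_of,
            fine_cells=pd.read_csv(indir / "population_baseline.csv"),
            exclusions=exclusions, images=images,
            detections=detections, truth_points=truth_points,
        )


def _footprint(row):
    return box(row["fx0"], row["fy0"], row["fx1"], row["fy1"])


def run_pipeline(
    world_cfg: WorldConfig | None,
    run_cfg: RunConfig,
    outdir: str | Path,
    inputs: PipelineInputs | None = None,
) -> dict:
    """Run every stage and return the manifest (also written as JSON)."""
    run_cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "files": {}, "config": _to_plain(run_cfg)}
    written: list[Path] = []

    def _save(df: pd.DataFrame, rel: str) -> None:
        p = outdir / rel
        p.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(p, index=False)
        written.append(p)

    # ---- stage: synth / ingest -------------------------------------------
    try:
        if inputs is None:
            if world_cfg is None:
                raise ValueError("either a world config or pipeline inputs are required")
            world = generate_world(world_cfg)
            written.extend(world.write(outdir / "world"))
            manifest["config_world"] = _to_plain(world_cfg)
            inputs = PipelineInputs.from_world(world)
        manifest["stages"]["synth"] = {
            "n_images": len(inputs.images),
            "n_detections": len(inputs.detections),
            "n_cities": len(inputs.aois),
        }
    except Exception as exc:
        raise StageError("synth", str(exc)) from exc

    # ---- stage: tune-threshold -------------------------------------------
    try:
        if inputs.truth_points is not None and len(inputs.truth_points):
            cars_only, _ = dp.filter_by_class(inputs.detections)
            sweep = dp.sweep_confidence_threshold(
                cars_only, inputs.truth_points,
                beta=run_cfg.tune_beta, step=run_cfg.tune_step,
                max_match_dist=run_cfg.match_dist_m)
            _save(sweep.to_frame(), "tune/fbeta_sweep.csv")
            manifest["stages"]["tune"] = {
                "beta": run_cfg.tune_beta,
                "n_thresholds": len(sweep.thresholds),
                "chosen_threshold": sweep.chosen_threshold,
                "max_fbeta": float(sweep.fbeta.max()),
            }
        else:
            manifest["stages"]["tune"] = {"skipped": "no ground-truth annotations supplied"}
    except Exception as exc:
        raise StageError("tune", str(exc)) from exc

    # ---- stage: filter ----------------------------------------------------
    try:
        dets, n_other = dp.filter_by_class(inputs.detections)
        n0 = len(dets)
        dets = dp.filter_by_confidence(dets, run_cfg.confidence_threshold)
        n_lowconf = n0 - len(dets)
        kept, removed = dp.filter_false_positives(dets, inputs.exclusions)
        _save(kept[["det_id", "image_id", "x", "y", "score", "class_label"]],
              "filter/detections_kept.csv")
        _save(removed[["det_id", "image_id", "x", "y", "score", "class_label"]],
              "filter/detections_removed_fp.csv")
        manifest["stages"]["filter"] = {
            "threshold": run_cfg.confidence_threshold,
            "removed_other_class": n_other,
            "removed_low_confidence": int(n_lowconf),
            "removed_exclusion_fp": len(removed),
            "kept": len(kept),
        }
    except Exception as exc:
        raise StageError("filter", str(exc)) from exc

    # ---- stage: screen ----------------------------------------------------
    try:
        per_image = kept.groupby("image_id").size()
        images = inputs.images.copy()
        images["n_detections"] = images["image_id"].map(per_image).fillna(0).astype(int)
        fine_by_aoi = {a: g for a, g in inputs.fine_cells.groupby("aoi_id")}
        rules = scr.ScreeningRules(
            min_pop_coverage_pct=run_cfg.min_pop_coverage_pct,
            cloud_drop=run_cfg.cloud_drop, cloud_review=run_cfg.cloud_review,
            low_count_flag=run_cfg.low_count_flag, min_area_pct=run_cfg.min_area_pct)
        report = scr.screen_images(images, fine_by_aoi, inputs.aois, rules)
        _save(report, "screen/screening_report.csv")
        kept_ids = set(report.loc[report["decision"] == "keep", "image_id"])
        images_kept = images[images["image_id"].isin(kept_ids)].copy()
        manifest["stages"]["screen"] = {
            "n_images_in": len(images),
            "n_images_kept": len(images_kept),
            "dropped": report[report["decision"] != "keep"]["decision"]
            .value_counts().to_dict(),
            "flagged_low_count": int(report["flags"].str.contains("low_count").sum()),
        }
    except Exception as exc:
        raise StageError("screen", str(exc)) from exc

    # ---- stage: dynamics --------------------------------------------------
    try:
        cut = pd.Timestamp(run_cfg.cut_date).tz_localize("UTC")
        pre_war_target = (
            (images_kept["year"] > run_cfg.baseline_year)
            & (images_kept["year"] == cut.year)
            & (pd.to_datetime(images_kept["acquired_at"], utc=True) < cut)
        )
        images_used = images_kept[~pre_war_target]
        grids: dict = {}
        count_parts = []
        n_outside = 0
        dets_by_img = {k: g for k, g in kept.groupby("image_id")}
        for aoi_id in sorted(inputs.aois):
            grid = car_dynamics.build_grid(
                inputs.aois[aoi_id], fine_by_aoi.get(aoi_id, pd.DataFrame(columns=["x0", "y0", "people"])),
                aoi_id=aoi_id, cell_size_m=run_cfg.cell_size_m)
            grids[aoi_id] = grid
            for _, img in images_used[images_used["aoi_id"] == aoi_id].iterrows():
                d = dets_by_img.get(img["image_id"], kept.iloc[0:0])
                counts, dropped = car_dynamics.count_cars_per_cell(
                    d, grid, footprint=_footprint(img),
                    coverage_threshold=run_cfg.cell_coverage_frac)
                n_outside += dropped
                counts.insert(0, "aoi_id", aoi_id)
                counts.insert(1, "image_id", img["image_id"])
                counts["year"] = img["year"]
                counts["month"] = img["month"]
                count_parts.append(counts)
        per_image_counts = (
            pd.concat(count_parts, ignore_index=True) if count_parts
            else pd.DataFrame(columns=["aoi_id", "image_id", "cell_id", "count",
                                       "covered", "year", "month"]))
        stats = car_dynamics.monthly_cell_means(per_image_counts)
        _save(stats, "dynamics/cell_month_stats.csv")
        grid_tables = pd.concat(
            [g.cells.assign(aoi_id=a) for a, g in grids.items()], ignore_index=True)
        _save(grid_tables, "dynamics/grid_cells.csv")
        change_parts = []
        for period in ("year", "quarter"):
            for level in ("aoi", "oblast"):
                ch = car_dynamics.relative_density_change(
                    stats, baseline_year=run_cfg.baseline_year,
                    cut_date=run_cfg.cut_date, period=period, level=level,
                    oblast_of=inputs.oblast_of)
                ch.insert(0, "level", level)
                ch.insert(1, "resolution", period)
                change_parts.append(ch)
        density_changes = pd.concat(change_parts, ignore_index=True)
        _save(density_changes, "dynamics/density_changes.csv")
        manifest["stages"]["dynamics"] = {
            "excluded_pre_cut_images": int(pre_war_target.sum()),
            "detections_outside_grid": int(n_outside),
            "n_cell_months": len(stats),
        }
    except Exception as exc:
        raise StageError("dynamics", str(exc)) from exc

    # ---- stage: estimate --------------------------------------------------
    try:
        area_pct = report.set_index("image_id")["area_pct"]
        images_used = images_used.assign(area_pct=images_used["image_id"].map(area_pct))
        month_area = images_used.groupby(["aoi_id", "year", "month"])["area_pct"].max()
        change_parts, summaries, excluded = [], [], []
        for aoi_id in sorted(inputs.aois):
            sub = stats[stats["aoi_id"] == aoi_id]
            if len(sub) == 0:
                excluded.append({"city": aoi_id, "reason": "no usable cell-month data"})
                continue
            apm = {
                (int(y), int(m)): float(v)
                for (a, y, m), v in month_area.items() if a == aoi_id
            }
            try:
                ch, summ = idp.estimate_city(
                    sub, grids[aoi_id].cells,
                    baseline_year=run_cfg.baseline_year,
                    comparison_years=run_cfg.comparison_years,
                    methods=run_cfg.methods,
                    gam_basis_dim=run_cfg.gam_basis_dim,
                    gam_min_cells=run_cfg.gam_min_cells,
                    area_pct_of_month=apm, city=aoi_id)
            except FitError as exc:
                excluded.append({"city": aoi_id, "reason": str(exc)})
                continue
            summ["matched_months"] = json.dumps(summ["matched_months"], sort_keys=True)
            change_parts.append(ch)
            summaries.append(summ)
        changes = (pd.concat(change_parts, ignore_index=True) if change_parts
                   else pd.DataFrame())
        _save(changes, "estimate/change_estimates.csv")
        _save(pd.DataFrame(summaries), "estimate/model_summaries.csv")
        _save(pd.DataFrame(excluded, columns=["city", "reason"]),
              "estimate/excluded_cities.csv")
        manifest["stages"]["estimate"] = {
            "n_cities_estimated": len(summaries),
            "n_cities_excluded": len(excluded),
            "empty_result": len(summaries) == 0,
        }
    except Exception as exc:
        raise StageError("estimate", str(exc)) from exc

    # ---- stage: imagery-glm ----------------------------------------------
    try:
        glm_images = images_kept.copy()
        areas = {
            a: inputs.aois[a] for a in inputs.aois
        }
        glm_images["area_km2"] = [
            _footprint(r).intersection(areas[r["aoi_id"]]).area / 1e6
            for _, r in glm_images.iterrows()
        ]
        try:
            fit = fit_feature_glm(glm_images)
            _save(fit.table, "glm/feature_glm.csv")
            diag = glm_diagnostics(fit, glm_images)
            _save(pd.DataFrame([diag]), "glm/feature_glm_diagnostics.csv")
            manifest["stages"]["imagery_glm"] = {
                "n_images": fit.n_images,
                "excluded_zero_density": fit.n_excluded_zero,
            }
        except FitError as exc:
            manifest["stages"]["imagery_glm"] = {"skipped": str(exc)}
    except Exception as exc:
        raise StageError("imagery_glm", str(exc)) from exc

    # ---- manifest ---------------------------------------------------------
    for p in sorted(written):
        manifest["files"][str(p.relative_to(outdir))] = sha256_file(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
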