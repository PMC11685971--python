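"""Synthetic multi-city world generator with exported ground truth.

The generator emulates the data a displacement-from-cars analysis consumes:
a fine (100 m) gridded baseline population surface per city, a monotone
population->car link with Poisson count noise, partial image footprints
with quality metadata (GSD, off-nadir, sun elevation, cloud, snow),
false-positive detections injected inside tagged exclusion polygons, and a
known multiplicative displacement scenario between a baseline year and
later years.  Coordinates are planar meters in a local Cartesian frame.

Everything is driven by a single integer seed: the same `WorldConfig`
yields a bit-identical world, including exported files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, box

from .config import FPModel, LinkModel, Scenario, WorldConfig, save_config
from .detection_processing import ExclusionLayer
from .errors import ConfigurationError
from .geo import cell_cover_fractions, write_geojson

DETECTION_COLUMNS = ["det_id", "image_id", "x", "y", "score", "class_label", "is_fp"]
IMAGE_COLUMNS = [
    "image_id", "aoi_id", "year", "month", "acquired_at",
    "fx0", "fy0", "fx1", "fy1", "gsd_m", "off_nadir_deg",
    "sun_elev_deg", "cloud_frac", "snow",
]


@dataclass
class GroundTruth:
    """Known truth the pipeline is later scored against."""

    true_population: pd.DataFrame   # aoi_id, year, x0, y0, people (fine cells)
    expected_cars: pd.DataFrame     # aoi_id, year, x0, y0, exp_cars (full visibility)
    truth_points: pd.DataFrame      # image_id, x, y, detected

    def city_totals(self, year: int) -> pd.Series:
        sub = self.true_population[self.true_population["year"] == year]
        return sub.groupby("aoi_id")["people"].sum()


@dataclass
class World:
    config: WorldConfig
    aois: dict                      # aoi_id -> shapely Polygon
    oblast_of: dict                 # aoi_id -> oblast_id
    fine_cells: pd.DataFrame        # aoi_id, x0, y0, people (baseline year)
    exclusions: ExclusionLayer
    exclusion_aoi: list             # aoi_id per exclusion polygon
    images: pd.DataFrame
    detections: pd.DataFrame
    truth: GroundTruth

    def footprint(self, row) -> Polygon:
        return box(row["fx0"], row["fy0"], row["fx1"], row["fy1"])

    def write(self, outdir: str | Path) -> list[Path]:
        """Export the world as GeoJSON/CSV plus its config; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []

        def _csv(df: pd.DataFrame, name: str) -> None:
            p = outdir / name
            df.to_csv(p, index=False)
            paths.append(p)

        aoi_ids = sorted(self.aois)
        p = outdir / "aois.geojson"
        write_geojson(
            p,
            [self.aois[a] for a in aoi_ids],
            [{"aoi_id": a, "oblast": self.oblast_of[a]} for a in aoi_ids],
        )
        paths.append(p)
        p = outdir / "exclusions.geojson"
        write_geojson(
            p,
            self.exclusions.polygons,
            [dict(t, aoi_id=a) for t, a in zip(self.exclusions.tags, self.exclusion_aoi)],
        )
        paths.append(p)
        _csv(self.fine_cells, "population_baseline.csv")
        _csv(self.images.assign(acquired_at=self.images["acquired_at"].astype(str)), "images.csv")
        _csv(self.detections[["image_id", "x", "y", "score", "class_label"]], "detections.csv")
        _csv(self.truth.true_population, "truth_population.csv")
        _csv(self.truth.expected_cars, "truth_expected_cars.csv")
        _csv(self.truth.truth_points, "truth_points.csv")
        _csv(self.detections, "truth_detection_labels.csv")
        p = outdir / "world_config.yaml"
        save_config(self.config, p)
        paths.append(p)
        return paths


def apply_displacement_scenario(baseline_cells: pd.DataFrame, scenario, year: int | None = None) -> pd.DataFrame:
    """Scale each cell's population by its city (or per-cell) multiplier.

    `scenario` may be a `Scenario` (requires `year`), a mapping
    aoi_id -> multiplier, or a per-cell array aligned with `baseline_cells`.
    """
    out = baseline_cells.copy()
    if isinstance(scenario, Scenario):
        if year is None:
            raise ValueError("year is required with a Scenario")
        mult = out["aoi_id"].map(lambda a: scenario.multiplier(year, a)).to_numpy()
    elif isinstance(scenario, Mapping):
        mult = out["aoi_id"].map(lambda a: float(scenario.get(a, 1.0))).to_numpy()
    else:
        mult = np.asarray(scenario, dtype=float)
        if mult.shape != (len(out),):
            raise ValueError("per-cell multiplier array length mismatch")
    if np.any(mult < 0):
        raise ConfigurationError("scenario.multipliers", "multipliers must be >= 0")
    out["people"] = out["people"].to_numpy() * mult
    return out


def _population_surface(cfg: WorldConfig, aoi_id: str, origin: tuple[float, float],
                        total: float, rng: np.random.Generator) -> pd.DataFrame:
    ox, oy = origin
    n = int(round(cfg.aoi_size_m / cfg.pop_cell_m))
    xs = ox + np.arange(n) * cfg.pop_cell_m
    ys = oy + np.arange(n) * cfg.pop_cell_m
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    cx = gx + cfg.pop_cell_m / 2.0
    cy = gy + cfg.pop_cell_m / 2.0
    pm = cfg.pop_model
    lo, hi = 0.1 * cfg.aoi_size_m, 0.9 * cfg.aoi_size_m
    centers = rng.uniform(lo, hi, size=(pm.hotspots_per_city, 2)) + np.array([ox, oy])
    dens = np.zeros(len(gx))
    for hx, hy in centers:
        dens += np.exp(-((cx - hx) ** 2 + (cy - hy) ** 2) / (2.0 * pm.hotspot_sd_m**2))
    if dens.sum() > 0:
        dens /= dens.sum()
    w = pm.uniform_floor / len(gx) + (1.0 - pm.uniform_floor) * dens
    w /= w.sum()
    return pd.DataFrame({"aoi_id": aoi_id, "x0": gx, "y0": gy, "people": total * w})


def _exclusion_polygons(cfg: WorldConfig, origin: tuple[float, float]) -> tuple[list[Polygon], list[dict]]:
    ox, oy = origin
    s = cfg.aoi_size_m
    water = Point(ox + 0.28 * s, oy + 0.30 * s).buffer(0.12 * s, quad_segs=16)
    forest = box(ox + 0.70 * s, oy + 0.72 * s, ox + 0.95 * s, oy + 0.95 * s)
    return [water, forest], [{"key": "natural", "value": "water"},
                             {"key": "landuse", "value": "forest"}]


def _uniform_in_rect(rng, n, x0, y0, x1, y1):
    return rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)


def sample_detections(
    footprint: Polygon,
    cloud_frac: float,
    snow: bool,
    cells: pd.DataFrame,
    link_model: LinkModel,
    fp_model: FPModel,
    exclusion_polys: Sequence[Polygon],
    rng: np.random.Generator,
    image_id: str = "img",
    pop_cell_m: float = 100.0,
    snow_detect_factor: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample car detections for one image.

    Per covered fine cell, the expected true-car count is the link mean
    attenuated by the covered fraction, cloud transparency (1 - cloud
    fraction) and, on snow days, the snow detectability factor.  True car
    points are uniform within cell-and-footprint; each enters the detector
    output independently with probability `link_model.detection_rate` and
    a high-skew confidence score.  False positives follow a Poisson point
    process inside exclusion polygons eroded by the placement margin, with
    low-skew scores.  Returns (detections, truth_points).
    """
    atten = (1.0 - float(cloud_frac)) * (snow_detect_factor if snow else 1.0)
    det_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    if not footprint.is_empty and atten > 0:
        cov = cell_cover_fractions(cells["x0"].to_numpy(), cells["y0"].to_numpy(),
                                   pop_cell_m, footprint)
        mu = link_model.expected_cars(cells["people"].to_numpy()) * cov * atten
        if link_model.count_noise == "poisson":
            counts = rng.poisson(mu)
        else:
            counts = np.round(mu).astype(np.int64)
        fx0, fy0, fx1, fy1 = footprint.bounds
        idx = np.nonzero(counts)[0]
        x0s = cells["x0"].to_numpy()
        y0s = cells["y0"].to_numpy()
        for i in idx:
            k = int(counts[i])
            cx0, cy0 = x0s[i], y0s[i]
            # cell-and-footprint overlap rectangle (footprints are rectangles;
            # general footprints are handled by rejection against the polygon)
            ix0, iy0 = max(cx0, fx0), max(cy0, fy0)
            ix1 = min(cx0 + pop_cell_m, fx1)
            iy1 = min(cy0 + pop_cell_m, fy1)
            if ix1 <= ix0 or iy1 <= iy0:
                continue
            px, py = _uniform_in_rect(rng, k, ix0, iy0, ix1, iy1)
            detected = rng.random(k) < link_model.detection_rate
            scores = rng.beta(*link_model.true_score, size=k)
            for j in range(k):
                truth_rows.append((image_id, px[j], py[j], bool(detected[j])))
                if detected[j]:
                    det_rows.append((image_id, px[j], py[j], scores[j], "small car", False))
        n_true = sum(1 for r in det_rows)
        n_other = rng.poisson(link_model.other_class_rate * n_true)
        if n_other > 0:
            px, py = _uniform_in_rect(rng, n_other, fx0, fy0, fx1, fy1)
            scores = rng.beta(*link_model.true_score, size=n_other)
            for j in range(n_other):
                det_rows.append((image_id, px[j], py[j], scores[j], "truck", False))
        # false positives: Poisson process inside eroded exclusion polygons
        if fp_model.intensity_per_km2 > 0:
            for poly in exclusion_polys:
                inner = poly.buffer(-fp_model.margin_m)
                if inner.is_empty:
                    continue
                region = inner.intersection(footprint)
                if region.is_empty or region.area <= 0:
                    continue
                lam = fp_model.intensity_per_km2 * region.area / 1e6 * atten
                n_fp = rng.poisson(lam)
                placed = 0
                bx0, by0, bx1, by1 = region.bounds
                guard = 0
                while placed < n_fp and guard < 10_000:
                    px, py = rng.uniform(bx0, bx1), rng.uniform(by0, by1)
                    guard += 1
                    if region.contains(Point(px, py)):
                        score = rng.beta(*link_model.fp_score)
                        det_rows.append((image_id, px, py, score, "small car", True))
                        placed += 1
    det = pd.DataFrame(det_rows, columns=["image_id", "x", "y", "score", "class_label", "is_fp"])
    truth = pd.DataFrame(truth_rows, columns=["image_id", "x", "y", "detected"])
    return det, truth


def _sample_image_metadata(im, year: int, month: int, seq: int, aoi_id: str,
                           origin, size_m: float, rng) -> dict:
    ox, oy = origin
    if rng.random() < im.full_cover_prob:
        fx0, fy0, fx1, fy1 = ox, oy, ox + size_m, oy + size_m
    else:
        frac = rng.uniform(*im.footprint_frac_range)
        side = np.sqrt(frac) * size_m
        fx0 = ox + rng.uniform(0.0, size_m - side)
        fy0 = oy + rng.uniform(0.0, size_m - side)
        fx1, fy1 = fx0 + side, fy0 + side
    u = rng.random()
    if u < im.full_cloud_prob:
        cloud = 1.0
    elif u < im.full_cloud_prob + im.cloud_zero_prob:
        cloud = 0.0
    else:
        cloud = float(rng.beta(*im.cloud_beta))
    snow = bool(month in im.snow_months and rng.random() < im.snow_prob)
    day = int(rng.integers(1, 29))
    minute = int(rng.integers(0, 60))
    acquired = pd.Timestamp(year=year, month=month, day=day, hour=8, minute=minute, tz="UTC")
    return {
        "image_id": f"{aoi_id}_{year}{month:02d}_{seq:02d}",
        "aoi_id": aoi_id,
        "year": year,
        "month": month,
        "acquired_at": acquired,
        "fx0": fx0, "fy0": fy0, "fx1": fx1, "fy1": fy1,
        "gsd_m": float(rng.choice(im.gsd_values, p=im.gsd_probs)),
        "off_nadir_deg": float(rng.uniform(*im.off_nadir_range)),
        "sun_elev_deg": float(rng.uniform(*im.sun_elev_range)),
        "cloud_frac": cloud,
        "snow": snow,
    }


def generate_world(config: WorldConfig) -> World:
    """Generate a self-consistent synthetic world from `config`.

    Deterministic for a fixed config (seed included): per-image random
    streams are spawned from one seed sequence in a fixed order.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_layout, rng_images = [np.random.default_rng(s) for s in ss.spawn(2)]

    size_m = config.aoi_size_m
    aois: dict = {}
    oblast_of: dict = {}
    origins: dict = {}
    fine_parts = []
    excl_polys: list[Polygon] = []
    excl_tags: list[dict] = []
    excl_aoi: list[str] = []
    populations = config.populations()

    for i, aoi_id in enumerate(config.city_ids()):
        ox = config.aoi_origin_offset_m + i * (size_m + config.aoi_gap_m)
        oy = config.aoi_origin_offset_m
        origins[aoi_id] = (ox, oy)
        aois[aoi_id] = box(ox, oy, ox + size_m, oy + size_m)
        oblast_of[aoi_id] = f"oblast_{i // 2}"
        polys, tags = _exclusion_polygons(config, (ox, oy))
        excl_polys.extend(polys)
        excl_tags.extend(tags)
        excl_aoi.extend([aoi_id] * len(polys))
        cells = _population_surface(config, aoi_id, (ox, oy), populations[i], rng_layout)
        # exclusion areas are uninhabited: zero population in any fine cell
        # touching an exclusion polygon, then rescale to preserve the total
        cx0 = cells["x0"].to_numpy()
        cy0 = cells["y0"].to_numpy()
        blocked = np.zeros(len(cells), dtype=bool)
        for poly in polys:
            frac = cell_cover_fractions(cx0, cy0, config.pop_cell_m, poly)
            blocked |= frac > 0
        people = cells["people"].to_numpy().copy()
        kept_total = people[~blocked].sum()
        if kept_total > 0:
            people[blocked] = 0.0
            people *= populations[i] / people.sum()
        cells["people"] = people
        fine_parts.append(cells)

    fine_cells = pd.concat(fine_parts, ignore_index=True)
    exclusions = ExclusionLayer(polygons=excl_polys, tags=excl_tags)
    exclusions.validate()

    # ground-truth populations & expected cars per period
    pop_parts, car_parts = [], []
    for year in sorted(config.months):
        displaced = apply_displacement_scenario(fine_cells, config.scenario, year)
        pop_parts.append(displaced.assign(year=year))
        car_parts.append(
            pd.DataFrame({
                "aoi_id": displaced["aoi_id"],
                "year": year,
                "x0": displaced["x0"],
                "y0": displaced["y0"],
                "exp_cars": config.link_model.expected_cars(displaced["people"].to_numpy()),
            })
        )
    true_population = pd.concat(pop_parts, ignore_index=True)[
        ["aoi_id", "year", "x0", "y0", "people"]]
    expected_cars = pd.concat(car_parts, ignore_index=True)

    pop_by_year = {
        y: g.set_index(["aoi_id", "x0", "y0"])["people"]
        for y, g in true_population.groupby("year")
    }

    image_rows = []
    det_parts = []
    truth_parts = []
    im = config.image_model
    for aoi_id in config.city_ids():
        for year in sorted(config.months):
            for month in config.months[year]:
                n_img = int(rng_images.poisson(im.mean_images_per_month))
                for seq in range(n_img):
                    meta = _sample_image_metadata(
                        im, year, month, seq, aoi_id, origins[aoi_id], size_m, rng_images)
                    image_rows.append(meta)
                    cells = fine_cells[fine_cells["aoi_id"] == aoi_id][["x0", "y0"]].copy()
                    cells["people"] = pop_by_year[year].loc[aoi_id].reindex(
                        list(zip(cells["x0"], cells["y0"]))).to_numpy()
                    city_polys = [p for p, a in zip(excl_polys, excl_aoi) if a == aoi_id]
                    det, truth = sample_detections(
                        box(meta["fx0"], meta["fy0"], meta["fx1"], meta["fy1"]),
                        meta["cloud_frac"], meta["snow"], cells,
                        config.link_model, config.fp_model, city_polys,
                        rng_images, image_id=meta["image_id"],
                        pop_cell_m=config.pop_cell_m,
                        snow_detect_factor=im.snow_detect_factor,
                    )
                    det_parts.append(det)
                    truth_parts.append(truth)

    images = pd.DataFrame(image_rows, columns=IMAGE_COLUMNS)
    det_parts = [d for d in det_parts if len(d)]
    detections = (
        pd.concat(det_parts, ignore_index=True)
        if det_parts else pd.DataFrame(columns=DETECTION_COLUMNS[1:])
    )
    detections.insert(0, "det_id", np.arange(len(detections), dtype=np.int64))
    truth_parts = [t for t in truth_parts if len(t)]
    truth_points = (
        pd.concat(truth_parts, ignore_index=True)
        if truth_parts else pd.DataFrame(columns=["image_id", "x", "y", "detected"])
    )

    truth = GroundTruth(
        true_population=true_population,
        expected_cars=expected_cars,
        truth_points=truth_points,
    )
    return World(
        config=config,
        aois=aois,
        oblast_of=oblast_of,
        fine_cells=fine_cells,
        exclusions=exclusions,
        exclusion_aoi=excl_aoi,
        images=images,
        detections=detections,
        truth=truth,
    )


def simulate_imagery_features(
    n: int,
    coeffs: Mapping[str, float] | None = None,
    sigma: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate image records from a log-linear car-density model.

    log density = b0 + b_res04*[GSD=0.4] + b_res05*[GSD=0.5] + b_snow*snow
    + b_off_nadir*off_nadir + b_sun_elev*sun_elev + b_cloud*cloud + noise.
    Returns an image table (with `n_detections` and `area_km2`) suitable
    for the imagery-feature model; used for coefficient-recovery checks.
    """
    defaults = {"b0": 2.0, "b_res04": 0.0, "b_res05": 0.0, "b_snow": 0.0,
                "b_off_nadir": 0.0, "b_sun_elev": 0.0, "b_cloud": 0.0}
    c = dict(defaults, **(coeffs or {}))
    rng = np.random.default_rng(seed)
    gsd = rng.choice([0.3, 0.4, 0.5], size=n)
    snow = rng.random(n) < 0.3
    off_nadir = rng.uniform(5.0, 40.0, n)
    sun = rng.uniform(20.0, 60.0, n)
    cloud = rng.uniform(0.0, 0.2, n)
    area = rng.uniform(5.0, 20.0, n)
    eta = (c["b0"] + c["b_res04"] * (gsd == 0.4) + c["b_res05"] * (gsd == 0.5)
           + c["b_snow"] * snow + c["b_off_nadir"] * off_nadir
           + c["b_sun_elev"] * sun + c["b_cloud"] * cloud
           + rng.normal(0.0, sigma, n))
    density = np.exp(eta)
    t0 = pd.Timestamp("2019-01-01T08:00:00Z")
    return pd.DataFrame({
        "image_id": [f"sim_{i:04d}" for i in range(n)],
        "acquired_at": [t0 + pd.Timedelta(days=int(i)) for i in range(n)],
        "gsd_m": gsd,
        "snow": snow,
        "off_nadir_deg": off_nadir,
        "sun_elev_deg": sun,
        "cloud_frac": cloud,
        "area_km2": area,
        "n_detections": density * area,
    })
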