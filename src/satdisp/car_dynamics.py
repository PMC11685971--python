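"""1 km analysis grid and gridded car dynamics.

Cars are aggregated on an axis-aligned 1 x 1 km grid snapped to multiples
of 1000 m in the world frame, so cell identities are stable across periods
and runs.  Per cell and month, the mean car count over covering images is
recorded; a cell counts as covered by an image when at least half of its
area (configurable) lies inside the footprint.  Relative change in average
car density (cars per covered km^2) versus the baseline year is computed
per city and, by averaging cities first, per oblast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .errors import GeometryError
from .geo import cell_cover_fractions, rect_overlap_fractions


@dataclass
class PopulationGrid:
    aoi_id: str
    cells: pd.DataFrame          # cell_id, x0, y0, baseline_people
    cell_size_m: float = 1000.0

    def cell_polygon(self, cell_id: str) -> Polygon:
        row = self.cells.set_index("cell_id").loc[cell_id]
        s = self.cell_size_m
        return box(row["x0"], row["y0"], row["x0"] + s, row["y0"] + s)


def cell_id_of(x0: float, y0: float) -> str:
    return f"{int(round(x0))}_{int(round(y0))}"


def build_grid(
    aoi: Polygon,
    fine_cells: pd.DataFrame,
    aoi_id: str = "aoi",
    cell_size_m: float = 1000.0,
    pop_cell_m: float = 100.0,
) -> PopulationGrid:
    """Build the snapped analysis grid over an AOI.

    Cells are excluded when they do not intersect the AOI.  Baseline
    people per cell come from area-weighted aggregation of the fine
    population cells (a fine cell straddling a coarse boundary is split by
    rectangle overlap).
    """
    if aoi.is_empty or aoi.area <= 0:
        raise GeometryError("AOI polygon is degenerate")
    minx, miny, maxx, maxy = aoi.bounds
    x_start = np.floor(minx / cell_size_m) * cell_size_m
    y_start = np.floor(miny / cell_size_m) * cell_size_m
    xs = np.arange(x_start, maxx, cell_size_m)
    ys = np.arange(y_start, maxy, cell_size_m)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    gx, gy = gx.ravel(), gy.ravel()
    inter = cell_cover_fractions(gx, gy, cell_size_m, aoi)
    keep = inter > 0
    gx, gy = gx[keep], gy[keep]

    people = np.zeros(len(gx))
    if len(fine_cells):
        fx = fine_cells["x0"].to_numpy(dtype=float)
        fy = fine_cells["y0"].to_numpy(dtype=float)
        fpop = fine_cells["people"].to_numpy(dtype=float)
        pos = {(x, y): i for i, (x, y) in enumerate(zip(gx, gy))}
        for j in range(len(fx)):
            # a fine cell overlaps at most 4 coarse cells
            for cx in np.unique([np.floor(fx[j] / cell_size_m),
                                 np.floor((fx[j] + pop_cell_m - 1e-9) / cell_size_m)]):
                for cy in np.unique([np.floor(fy[j] / cell_size_m),
                                     np.floor((fy[j] + pop_cell_m - 1e-9) / cell_size_m)]):
                    key = (cx * cell_size_m, cy * cell_size_m)
                    i = pos.get(key)
                    if i is None:
                        continue
                    frac = rect_overlap_fractions(
                        np.array([fx[j]]), np.array([fy[j]]), pop_cell_m,
                        key[0], key[1], key[0] + cell_size_m, key[1] + cell_size_m)[0]
                    people[i] += fpop[j] * frac
    cells = pd.DataFrame({
        "cell_id": [cell_id_of(x, y) for x, y in zip(gx, gy)],
        "x0": gx,
        "y0": gy,
        "baseline_people": people,
    }).sort_values("cell_id", ignore_index=True)
    return PopulationGrid(aoi_id=aoi_id, cells=cells, cell_size_m=cell_size_m)


def count_cars_per_cell(
    detections: pd.DataFrame,
    grid: PopulationGrid,
    footprint: Polygon | None = None,
    coverage_threshold: float = 0.5,
) -> tuple[pd.DataFrame, int]:
    """Assign filtered detections to grid cells for one image.

    Each detection lands in exactly one cell via half-open intervals
    [x0, x0+s) x [y0, y0+s); detections outside the grid are dropped and
    counted.  Cells are marked covered when >= `coverage_threshold` of
    their area lies inside the footprint (all covered if no footprint is
    given).  Returns (per-cell frame with count and covered, n_dropped).
    """
    s = grid.cell_size_m
    cells = grid.cells
    counts = pd.Series(0, index=cells["cell_id"], dtype=np.int64)
    n_dropped = 0
    if len(detections):
        cx = np.floor(detections["x"].to_numpy(dtype=float) / s) * s
        cy = np.floor(detections["y"].to_numpy(dtype=float) / s) * s
        ids = pd.Series([cell_id_of(x, y) for x, y in zip(cx, cy)])
        in_grid = ids.isin(counts.index)
        n_dropped = int((~in_grid).sum())
        vc = ids[in_grid.to_numpy()].value_counts()
        counts.loc[vc.index] = vc.to_numpy()
    if footprint is None:
        covered = np.ones(len(cells), dtype=bool)
    else:
        frac = cell_cover_fractions(
            cells["x0"].to_numpy(), cells["y0"].to_numpy(), s, footprint)
        covered = frac >= coverage_threshold
    out = pd.DataFrame({
        "cell_id": cells["cell_id"].to_numpy(),
        "count": counts.to_numpy(),
        "covered": covered,
    })
    return out, n_dropped


def monthly_cell_means(per_image_counts: pd.DataFrame) -> pd.DataFrame:
    """Per cell-month mean car count over the images covering the cell.

    Input rows: aoi_id, image_id, year, month, cell_id, count, covered.
    Uncovered cell-images do not contribute; cell-months with no covering
    image are absent from the output (never imputed as zero).
    """
    cov = per_image_counts[per_image_counts["covered"]]
    if len(cov) == 0:
        return pd.DataFrame(columns=["aoi_id", "cell_id", "year", "month",
                                     "mean_cars", "n_images"])
    g = cov.groupby(["aoi_id", "cell_id", "year", "month"], as_index=False).agg(
        mean_cars=("count", "mean"), n_images=("count", "size"))
    return g


def monthly_city_density(stats: pd.DataFrame, cell_area_km2: float = 1.0) -> pd.DataFrame:
    """Mean car density (cars per covered km^2) per city and month."""
    g = stats.groupby(["aoi_id", "year", "month"], as_index=False).agg(
        total_cars=("mean_cars", "sum"), n_cells=("cell_id", "size"))
    g["density"] = g["total_cars"] / (g["n_cells"] * cell_area_km2)
    return g


def _period_of(row, baseline_year: int, cut_date: pd.Timestamp, period: str):
    """Assign a month to 'baseline', a target period label, or None."""
    ts = pd.Timestamp(year=int(row["year"]), month=int(row["month"]), day=28, tz="UTC")
    if row["year"] == baseline_year:
        return "baseline"
    if ts < cut_date:
        return None
    if period == "year":
        return str(int(row["year"]))
    q = (int(row["month"]) - 1) // 3 + 1
    return f"{int(row['year'])}Q{q}"


def relative_density_change(
    stats: pd.DataFrame,
    baseline_year: int = 2019,
    cut_date: str | pd.Timestamp = "2022-02-24",
    period: str = "year",
    level: str = "aoi",
    oblast_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Percent change in average car density versus the baseline year.

    Months are assigned to the baseline or to target periods (calendar
    quarters or whole years, months before the cut date excluded); the
    density per unit-period is the mean of its monthly densities.  At
    oblast level, city densities are averaged across the oblast's cities
    before the change is taken.  Units missing data in either period are
    reported with pct_change missing and a reason, never as zero.
    """
    if level == "oblast" and oblast_of is None:
        raise ValueError("oblast_of mapping required at oblast level")
    cut = pd.Timestamp(cut_date)
    if cut.tzinfo is None:
        cut = cut.tz_localize("UTC")
    dens = monthly_city_density(stats)
    dens["period"] = dens.apply(_period_of, axis=1,
                                baseline_year=baseline_year, cut_date=cut, period=period)
    dens = dens[dens["period"].notna()]
    per = dens.groupby(["aoi_id", "period"], as_index=False)["density"].mean()
    if level == "oblast":
        per["unit"] = per["aoi_id"].map(oblast_of)
        per = per.groupby(["unit", "period"], as_index=False)["density"].mean()
    else:
        per = per.rename(columns={"aoi_id": "unit"})
    wide = per.pivot(index="unit", columns="period", values="density")
    targets = [c for c in wide.columns if c != "baseline"]
    rows = []
    for unit, r in wide.iterrows():
        base = r.get("baseline", np.nan)
        for t in targets:
            d = r.get(t, np.nan)
            if np.isnan(base) or np.isnan(d):
                rows.append({"unit": unit, "period": t, "baseline_density": base,
                             "period_density": d, "pct_change": np.nan,
                             "reason": "missing data in baseline or target period"})
            elif base == 0.0:
                rows.append({"unit": unit, "period": t, "baseline_density": base,
                             "period_density": d, "pct_change": np.nan,
                             "reason": "baseline density is zero"})
            else:
                rows.append({"unit": unit, "period": t, "baseline_density": base,
                             "period_density": d,
                             "pct_change": 100.0 * (d - base) / base, "reason": ""})
    return pd.DataFrame(rows)
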