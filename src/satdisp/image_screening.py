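"""Image screening: population representativeness, cloud, and low counts.

An image is kept only if it is informative about its city: it must cover a
sufficient share of the baseline population (the coverage index, percent of
the AOI's people under the footprint, must be at least 50 by default),
must not be cloud-obstructed, and must cover at least 1% of the AOI area
(an ingest contract re-checked defensively).  Kept images with fewer than
10 detections are flagged as suspicious rather than dropped.  Dropped
images are never discarded silently: the report retains every image with
its decision and reason.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .errors import DomainError, GeometryError
from .geo import cell_cover_fractions


@dataclass
class ScreeningRules:
    min_pop_coverage_pct: float = 50.0
    cloud_drop: float = 0.95        # effective full obstruction
    cloud_review: float = 0.5       # partial obstruction -> review flag
    low_count_flag: int = 10
    min_area_pct: float = 1.0


def population_coverage_index(
    footprint: Polygon,
    fine_cells: pd.DataFrame,
    pop_cell_m: float = 100.0,
) -> float:
    """Percent of the AOI's people lying under the image footprint.

    People in fine cells straddling the footprint boundary are apportioned
    by intersection-area fraction (unbiased under uniform within-cell
    density).  Raises if the AOI holds no people.
    """
    total = float(fine_cells["people"].sum())
    if total <= 0.0:
        raise DomainError("AOI has zero total population: coverage index undefined")
    frac = cell_cover_fractions(
        fine_cells["x0"].to_numpy(), fine_cells["y0"].to_numpy(), pop_cell_m, footprint)
    covered = float((fine_cells["people"].to_numpy() * frac).sum())
    return 100.0 * covered / total


def aoi_area_coverage(footprint: Polygon, aoi: Polygon) -> float:
    """Percent of the AOI area covered by the footprint."""
    if aoi.is_empty or aoi.area <= 0.0:
        raise GeometryError("degenerate AOI with zero area")
    return 100.0 * footprint.intersection(aoi).area / aoi.area


def screen_images(
    images: pd.DataFrame,
    fine_cells_by_aoi: Mapping[str, pd.DataFrame],
    aois: Mapping[str, Polygon],
    rules: ScreeningRules | None = None,
    pop_cell_m: float = 100.0,
    footprint_of=None,
) -> pd.DataFrame:
    """Screen every image; returns the report (one row per image).

    decision is one of keep / drop_area / drop_cloud / drop_population,
    mutually exclusive, evaluated in that order; `flag_low_count` and
    `flag_cloud_review` may co-occur with keep.  Requires an
    `n_detections` column (post detection-filter counts).
    """
    from shapely.geometry import box

    rules = rules or ScreeningRules()
    if footprint_of is None:
        footprint_of = lambda row: box(row["fx0"], row["fy0"], row["fx1"], row["fy1"])
    rows = []
    for _, img in images.iterrows():
        fp = footprint_of(img)
        aoi = aois[img["aoi_id"]]
        cells = fine_cells_by_aoi[img["aoi_id"]]
        area_pct = aoi_area_coverage(fp, aoi)
        p_pct = population_coverage_index(fp, cells, pop_cell_m)
        flags = []
        if area_pct < rules.min_area_pct:
            decision, reason = "drop_area", f"covers {area_pct:.2f}% of AOI area (<{rules.min_area_pct}%)"
        elif img["cloud_frac"] >= rules.cloud_drop:
            decision, reason = "drop_cloud", f"cloud fraction {img['cloud_frac']:.2f} >= {rules.cloud_drop}"
        elif p_pct < rules.min_pop_coverage_pct:
            decision, reason = "drop_population", (
                f"covers {p_pct:.1f}% of population (<{rules.min_pop_coverage_pct}%)")
        else:
            decision, reason = "keep", ""
            if img["cloud_frac"] >= rules.cloud_review:
                flags.append("cloud_review")
            if int(img.get("n_detections", 0)) < rules.low_count_flag:
                flags.append("low_count")
        rows.append({
            "image_id": img["image_id"],
            "aoi_id": img["aoi_id"],
            "p_pct": p_pct,
            "area_pct": area_pct,
            "decision": decision,
            "flags": "|".join(flags),
            "reason": reason,
        })
    return pd.DataFrame(rows)
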