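"""Planar-geometry helpers.

All coordinates in this package are planar meters in a local Cartesian
frame (a metric projected CRS on real data).  GeoJSON is read and written
with shapely + json; properties travel as plain dicts.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon, box, mapping, shape

from .errors import GeometryError


def is_axis_aligned_rectangle(poly: Polygon) -> bool:
    return poly.equals(box(*poly.bounds))


def rect_overlap_fractions(
    cells_x0: np.ndarray,
    cells_y0: np.ndarray,
    cell_size: float,
    rx0: float,
    ry0: float,
    rx1: float,
    ry1: float,
) -> np.ndarray:
    """Fraction of each axis-aligned square cell covered by a rectangle.

    Vectorized over cells; exact for axis-aligned geometry.
    """
    ox = np.clip(np.minimum(cells_x0 + cell_size, rx1) - np.maximum(cells_x0, rx0), 0.0, None)
    oy = np.clip(np.minimum(cells_y0 + cell_size, ry1) - np.maximum(cells_y0, ry0), 0.0, None)
    return (ox * oy) / (cell_size * cell_size)


def cell_cover_fractions(
    cells_x0: np.ndarray, cells_y0: np.ndarray, cell_size: float, footprint: Polygon
) -> np.ndarray:
    """Fraction of each square cell inside `footprint`.

    Uses exact rectangle arithmetic when the footprint is an axis-aligned
    rectangle, otherwise per-cell polygon intersection with a bounding-box
    prefilter.
    """
    cells_x0 = np.asarray(cells_x0, dtype=float)
    cells_y0 = np.asarray(cells_y0, dtype=float)
    if footprint.is_empty:
        return np.zeros(len(cells_x0))
    if is_axis_aligned_rectangle(footprint):
        rx0, ry0, rx1, ry1 = footprint.bounds
        return rect_overlap_fractions(cells_x0, cells_y0, cell_size, rx0, ry0, rx1, ry1)
    fx0, fy0, fx1, fy1 = footprint.bounds
    out = np.zeros(len(cells_x0))
    maybe = (
        (cells_x0 < fx1)
        & (cells_x0 + cell_size > fx0)
        & (cells_y0 < fy1)
        & (cells_y0 + cell_size > fy0)
    )
    area = cell_size * cell_size
    for i in np.nonzero(maybe)[0]:
        cell = box(cells_x0[i], cells_y0[i], cells_x0[i] + cell_size, cells_y0[i] + cell_size)
        out[i] = cell.intersection(footprint).area / area
    return out


def validate_polygon(poly: Polygon, index: int | None = None) -> Polygon:
    """Repair-or-reject polygon validation; names the polygon index on failure."""
    if poly.is_valid:
        return poly
    repaired = poly.buffer(0)
    if repaired.is_valid and not repaired.is_empty and repaired.geom_type == "Polygon":
        return repaired
    where = f" at index {index}" if index is not None else ""
    raise GeometryError(f"invalid polygon{where}: {poly.wkt[:80]}")


def write_geojson(path: str | Path, geoms: Sequence, properties: Sequence[dict]) -> None:
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": dict(p)}
        for g, p in zip(geoms, properties)
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload, sort_keys=True))


def read_geojson(path: str | Path) -> list[tuple[Polygon, dict]]:
    payload = json.loads(Path(path).read_text())
    return [(shape(f["geometry"]), f.get("properties") or {}) for f in payload["features"]]


def sha256_file(path: str | Path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
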