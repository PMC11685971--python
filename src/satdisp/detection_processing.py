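"""Detection post-processing: confidence-threshold tuning and
exclusion-polygon false-positive filtering.

The detector emits point candidates with confidence scores.  The working
threshold is tuned by sweeping thresholds and scoring each against
ground-truth car annotations with the F_beta statistic,

    F_beta = (1 + beta^2) * P * R / (beta^2 * P + R),

with beta = 0.5 by default so precision outweighs recall (false positives
are the costlier error when detections proxy for population).  Detections
that fall inside tagged land-use exclusion polygons (water, forest,
cropland, ...) are treated as false positives and removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely import STRtree
from shapely.geometry import Point, Polygon

from .errors import DomainError, GeometryError
from .geo import read_geojson, validate_polygon, write_geojson

ONLY_CLASS = "small car"


def fbeta_score(precision: float, recall: float, beta: float) -> float:
    """F_beta of a precision/recall pair; 0 when the denominator vanishes."""
    if not 0.0 <= precision <= 1.0:
        raise DomainError(f"precision {precision} outside [0, 1]")
    if not 0.0 <= recall <= 1.0:
        raise DomainError(f"recall {recall} outside [0, 1]")
    if beta <= 0:
        raise DomainError(f"beta {beta} must be > 0")
    denom = beta * beta * precision + recall
    if denom == 0.0:
        return 0.0
    return (1.0 + beta * beta) * precision * recall / denom


def greedy_match(det_xy: np.ndarray, truth_xy: np.ndarray, max_dist: float) -> int:
    """One-to-one greedy nearest matching within `max_dist`; returns #matches.

    Candidate pairs within range are accepted in increasing distance order,
    each detection and each truth point used at most once.
    """
    if len(det_xy) == 0 or len(truth_xy) == 0:
        return 0
    tree = cKDTree(truth_xy)
    pairs = tree.query_ball_point(det_xy, r=max_dist)
    cand = [
        (float(np.hypot(*(det_xy[i] - truth_xy[j]))), i, j)
        for i, js in enumerate(pairs) for j in js
    ]
    cand.sort()
    used_d: set = set()
    used_t: set = set()
    n = 0
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        n += 1
    return n


@dataclass
class FBetaSweep:
    beta: float
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    fbeta: np.ndarray
    chosen_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "threshold": self.thresholds,
            "precision": self.precision,
            "recall": self.recall,
            "fbeta": self.fbeta,
        })


def sweep_confidence_threshold(
    detections: pd.DataFrame,
    truth_points: pd.DataFrame,
    beta: float = 0.5,
    step: float = 0.05,
    max_match_dist: float = 2.5,
) -> FBetaSweep:
    """Sweep confidence thresholds 0..1 and pick the F_beta-maximizing one.

    At each threshold, detections scoring >= threshold are matched
    one-to-one to truth annotations within `max_match_dist` meters.
    Ties on max F_beta resolve to the largest threshold (precision-leaning).
    """
    if not 0.0 < step < 1.0:
        raise DomainError("step must be in (0, 1)")
    if len(truth_points) == 0:
        raise DomainError("truth_points is empty: precision/recall undefined")
    n_steps = int(round(1.0 / step))
    thresholds = np.round(np.arange(n_steps + 1) * step, 10)
    thresholds = thresholds[thresholds <= 1.0 + 1e-12]
    truth_xy = truth_points[["x", "y"]].to_numpy(dtype=float)
    scores = detections["score"].to_numpy(dtype=float)
    det_xy = detections[["x", "y"]].to_numpy(dtype=float)
    prec = np.zeros(len(thresholds))
    rec = np.zeros(len(thresholds))
    fb = np.zeros(len(thresholds))
    for k, tau in enumerate(thresholds):
        keep = scores >= tau
        n_det = int(keep.sum())
        tp = greedy_match(det_xy[keep], truth_xy, max_match_dist)
        p = tp / n_det if n_det else 1.0
        r = tp / len(truth_xy)
        prec[k], rec[k] = p, r
        fb[k] = fbeta_score(p, r, beta)
    best = fb.max()
    chosen = float(thresholds[np.nonzero(fb >= best - 1e-12)[0][-1]])
    return FBetaSweep(beta=beta, thresholds=thresholds, precision=prec,
                      recall=rec, fbeta=fb, chosen_threshold=chosen)


def filter_by_confidence(detections: pd.DataFrame, threshold: float) -> pd.DataFrame:
    if not 0.0 <= threshold <= 1.0:
        raise DomainError(f"threshold {threshold} outside [0, 1]")
    return detections[detections["score"] >= threshold]


def filter_by_class(detections: pd.DataFrame, keep_class: str = ONLY_CLASS
                    ) -> tuple[pd.DataFrame, int]:
    """Keep only one detector class; returns (kept, n_dropped)."""
    mask = detections["class_label"] == keep_class
    return detections[mask], int((~mask).sum())


@dataclass
class ExclusionLayer:
    """Tagged exclusion polygons (OSM-style key/value land-use layers)."""

    polygons: list = field(default_factory=list)
    tags: list = field(default_factory=list)

    ALLOWED_KEYS = ("landuse", "place", "natural", "leisure", "aeroway")

    def validate(self) -> "ExclusionLayer":
        self.polygons = [validate_polygon(p, i) for i, p in enumerate(self.polygons)]
        return self

    def to_geojson(self, path: str | Path) -> None:
        write_geojson(path, self.polygons, self.tags)

    @classmethod
    def from_geojson(cls, path: str | Path) -> "ExclusionLayer":
        feats = read_geojson(path)
        return cls(polygons=[g for g, _ in feats], tags=[p for _, p in feats]).validate()


def filter_false_positives(
    detections: pd.DataFrame, layer: ExclusionLayer
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition detections into (kept, removed) by exclusion polygons.

    A detection is removed iff its point lies inside or on the boundary of
    any exclusion polygon.  The two frames partition the input exactly.
    """
    layer.validate()
    if len(detections) == 0 or not layer.polygons:
        return detections, detections.iloc[0:0]
    import shapely

    pts = shapely.points(detections["x"].to_numpy(), detections["y"].to_numpy())
    tree = STRtree(pts)
    removed_mask = np.zeros(len(detections), dtype=bool)
    for poly in layer.polygons:
        idx = tree.query(poly, predicate="intersects")
        removed_mask[idx] = True
    return detections[~removed_mask], detections[removed_mask]
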