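import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import Point, Polygon, box

from satdisp.detection_processing import (
    ExclusionLayer,
    fbeta_score,
    filter_by_class,
    filter_by_confidence,
    filter_false_positives,
    greedy_match,
    sweep_confidence_threshold,
)
from satdisp.errors import DomainError, GeometryError


@pytest.mark.parametrize(
    "p, r, beta, expected, tol",
    [
        (0.5578, 0.3032, 0.5, 0.4776, 5e-5),   # detector's operating point
        (0.8, 0.4, 1.0, 8 / 15, 1e-12),        # harmonic mean at beta=1
        (0.3, 0.3, 0.5, 0.3, 1e-12),           # P = R collapses to the common value
        (0.7, 0.7, 2.0, 0.7, 1e-12),
        (0.0, 0.0, 0.5, 0.0, 0.0),             # zero denominator convention
        (1.0, 0.0, 1.0, 0.0, 0.0),
    ],
)
def test_fbeta_values(p, r, beta, expected, tol):
    assert fbeta_score(p, r, beta) == pytest.approx(expected, abs=tol)


@pytest.mark.parametrize("p, r, beta", [(-0.1, 0.5, 0.5), (0.5, 1.2, 0.5), (0.5, 0.5, 0.0)])
def test_fbeta_domain_errors(p, r, beta):
    with pytest.raises(DomainError):
        fbeta_score(p, r, beta)


def test_fbeta_monotone_in_precision_and_recall():
    grid = np.linspace(0.05, 1.0, 15)
    for beta in (0.5, 1.0, 2.0):
        for fixed in grid:
            along_p = [fbeta_score(p, fixed, beta) for p in grid]
            along_r = [fbeta_score(fixed, r, beta) for r in grid]
            assert np.all(np.diff(along_p) > -1e-15)
            assert np.all(np.diff(along_r) > -1e-15)


def _oracle_greedy(det_xy, truth_xy, max_dist):
    """Quadratic-time reference matcher: repeatedly take the closest pair."""
    pairs = [
        (float(np.hypot(dx - tx, dy - ty)), i, j)
        for i, (dx, dy) in enumerate(det_xy)
        for j, (tx, ty) in enumerate(truth_xy)
        if np.hypot(dx - tx, dy - ty) <= max_dist
    ]
    pairs.sort()
    used_d, used_t, n = set(), set(), 0
    for _, i, j in pairs:
        if i not in used_d and j not in used_t:
            used_d.add(i)
            used_t.add(j)
            n += 1
    return n


def _mixture(seed, n_true=120, n_fp=60):
    rng = np.random.default_rng(seed)
    truth = rng.uniform(0, 500, size=(n_true, 2))
    det_true = truth + rng.normal(0, 0.5, size=truth.shape)
    det_fp = rng.uniform(0, 500, size=(n_fp, 2))
    det = pd.DataFrame(
        {
            "x": np.concatenate([det_true[:, 0], det_fp[:, 0]]),
            "y": np.concatenate([det_true[:, 1], det_fp[:, 1]]),
            "score": np.concatenate(
                [rng.beta(8, 2, n_true), rng.beta(2, 5, n_fp)]
            ),
        }
    )
    truth_df = pd.DataFrame({"x": truth[:, 0], "y": truth[:, 1]})
    return det, truth_df


def test_sweep_threshold_count_and_argmax_oracle():
    det, truth = _mixture(3)
    sweep = sweep_confidence_threshold(det, truth, beta=0.5, step=0.05)
    assert len(sweep.thresholds) == 21
    assert np.all(np.diff(sweep.thresholds) > 0)
    # independent exhaustive recomputation with the quadratic matcher
    fb = []
    for tau in sweep.thresholds:
        sel = det[det["score"] >= tau]
        tp = _oracle_greedy(sel[["x", "y"]].to_numpy(), truth[["x", "y"]].to_numpy(), 2.5)
        p = tp / len(sel) if len(sel) else 1.0
        r = tp / len(truth)
        fb.append(fbeta_score(p, r, 0.5))
    fb = np.array(fb)
    best = fb.max()
    oracle_choice = sweep.thresholds[np.nonzero(fb >= best - 1e-12)[0][-1]]
    assert sweep.chosen_threshold == pytest.approx(oracle_choice)
    assert np.allclose(sweep.fbeta, fb)
    # recall is monotone non-increasing in the threshold
    assert np.all(np.diff(sweep.recall) <= 1e-12)


def test_sweep_perfect_detections():
    rng = np.random.default_rng(0)
    truth = pd.DataFrame({"x": rng.uniform(0, 100, 30), "y": rng.uniform(0, 100, 30)})
    det = truth.assign(score=0.9)
    sweep = sweep_confidence_threshold(det, truth, beta=0.5, step=0.05)
    upto = sweep.thresholds <= 0.9
    assert np.all(sweep.precision[upto] == 1.0)
    assert np.all(sweep.recall[upto] == 1.0)


def test_sweep_requires_truth():
    det, _ = _mixture(0)
    with pytest.raises(DomainError):
        sweep_confidence_threshold(det, pd.DataFrame(columns=["x", "y"]))


def test_filter_by_confidence_boundary():
    det = pd.DataFrame({"x": [0, 1, 2], "y": [0, 0, 0], "score": [0.44, 0.45, 0.46]})
    assert len(filter_by_confidence(det, 0.45)) == 2      # boundary inclusive
    assert filter_by_confidence(det, 0.0).equals(det)
    assert len(filter_by_confidence(det, 1.0)) == 0


def test_filter_by_class_counts():
    det = pd.DataFrame({"class_label": ["small car", "truck", "small car"]})
    kept, dropped = filter_by_class(det)
    assert len(kept) == 2 and dropped == 1


def test_false_positive_filter_partition_and_boundary():
    water = box(0, 0, 10, 10)
    layer = ExclusionLayer(polygons=[water], tags=[{"key": "natural", "value": "water"}])
    det = pd.DataFrame(
        {"x": [5.0, 10.0, 15.0], "y": [5.0, 5.0, 5.0], "score": [0.9, 0.9, 0.9]}
    )
    kept, removed = filter_false_positives(det, layer)
    # strictly inside and on the boundary are removed; outside kept
    assert list(removed["x"]) == [5.0, 10.0]
    assert list(kept["x"]) == [15.0]
    assert len(kept) + len(removed) == len(det)
    assert set(kept.index).isdisjoint(set(removed.index))


def test_false_positive_filter_empty_layer():
    det = pd.DataFrame({"x": [1.0], "y": [1.0], "score": [0.5]})
    kept, removed = filter_false_positives(det, ExclusionLayer())
    assert kept.equals(det) and len(removed) == 0


def test_invalid_polygon_names_index():
    degenerate = Polygon([(0, 0), (1, 1), (2, 2)])  # zero area, unrepairable
    layer = ExclusionLayer(polygons=[box(0, 0, 1, 1), degenerate], tags=[{}, {}])
    with pytest.raises(GeometryError, match="index 1"):
        layer.validate()


def test_self_intersecting_polygon_is_repaired():
    bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
    layer = ExclusionLayer(polygons=[bowtie], tags=[{}]).validate()
    assert layer.polygons[0].is_valid


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_false_positive_partition_property(seed):
    rng = np.random.default_rng(seed)
    det = pd.DataFrame({"x": rng.uniform(0, 50, 40), "y": rng.uniform(0, 50, 40),
                        "score": rng.random(40)})
    polys = [Point(rng.uniform(0, 50), rng.uniform(0, 50)).buffer(rng.uniform(1, 8))
             for _ in range(3)]
    layer = ExclusionLayer(polygons=polys, tags=[{}] * 3)
    kept, removed = filter_false_positives(det, layer)
    assert len(kept) + len(removed) == len(det)
    recombined = pd.concat([kept, removed]).sort_index()
    assert recombined.equals(det)


def test_greedy_match_one_to_one():
    truth = np.array([[0.0, 0.0]])
    det = np.array([[0.5, 0.0], [0.6, 0.0], [0.7, 0.0]])
    assert greedy_match(det, truth, 2.5) == 1  # a truth point matches once
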