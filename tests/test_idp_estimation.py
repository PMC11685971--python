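import numpy as np
import pandas as pd
import pytest

from satdisp import idp_estimation as idp
from satdisp.errors import FitError


def _presence(aoi, year_months):
    return pd.DataFrame(
        [{"aoi_id": aoi, "year": y, "month": m} for y, ms in year_months.items() for m in ms])


def test_match_months_intersections():
    p = _presence("a", {2019: [3, 4], 2022: [4, 7]})
    assert idp.match_months(p, 2019, [2020, 2022])["a"] == {2020: [], 2022: [4]}
    p = _presence("b", {2019: [5], 2020: [5], 2022: []})
    m = idp.match_months(p, 2019, [2020, 2022])["b"]
    assert m == {2020: [5], 2022: []}


def _stats(rows):
    return pd.DataFrame(rows, columns=["aoi_id", "cell_id", "year", "month",
                                       "mean_cars", "n_images"])


def test_pool_baseline():
    grid = pd.DataFrame({"cell_id": ["c1", "c2"], "baseline_people": [100.0, 40.0]})
    stats = _stats([
        ("a", "c1", 2019, 4, 2.0, 1), ("a", "c1", 2019, 5, 4.0, 1),
        ("a", "c2", 2019, 5, 7.0, 1),           # ragged: c2 seen in May only
        ("a", "c1", 2022, 4, 1.0, 1),           # non-baseline ignored
    ])
    pooled = idp.pool_baseline(stats, grid, 2019).set_index("cell_id")
    assert pooled.loc["c1", "mean_cars"] == pytest.approx(3.0)
    assert pooled.loc["c2", "mean_cars"] == pytest.approx(7.0)
    assert pooled.loc["c1", "people"] == pytest.approx(100.0)
    assert pooled.loc["c2", "n_months"] == 1


def _table(cars, people):
    return pd.DataFrame({"cell_id": [f"c{i}" for i in range(len(cars))],
                         "mean_cars": cars, "people": people})


def test_fit_ratio_values_and_median_imputation():
    t = _table([2.0, 1.0, 1.0, 0.0], [10.0, 4.0, 10.0, 50.0])
    m = idp.fit_ratio(t)
    assert m.ratios["c0"] == pytest.approx(5.0)
    # defined ratios {5, 4, 10}: the zero-car cell borrows the median 5
    assert m.fallback_ratio == pytest.approx(5.0)
    assert m.ratios["c3"] == pytest.approx(5.0)
    assert m.n_imputed == 1


def test_fit_ratio_degenerate_cases():
    with pytest.raises(FitError):
        idp.fit_ratio(_table([0.0, 0.0], [5.0, 5.0]))
    m = idp.fit_ratio(_table([1.0, 2.0], [0.0, 0.0]))
    assert m.fallback_ratio == 0.0
    assert (m.ratios == 0.0).all()


def test_predict_ratio_zero_cars_zero_people():
    m = idp.fit_ratio(_table([2.0], [10.0]))
    pred, n_excl = idp.predict_ratio(m, pd.Series([1.0, 0.0], index=["c0", "c0b"]))
    assert pred["c0"] == pytest.approx(5.0)
    assert n_excl == 1  # c0b has no baseline ratio


def test_ratio_method_exact_in_noiseless_proportional_world():
    """people = 50 x cars cell-wise; any displacement field is recovered
    exactly because the per-cell ratio is the true constant."""
    rng = np.random.default_rng(0)
    cars = rng.uniform(0.5, 40, 60)
    people = 50.0 * cars
    baseline = _table(cars, people)
    model = idp.fit_ratio(baseline)
    for mult in (0.6, np.full(60, 0.35), rng.uniform(0, 2, 60)):
        displaced_people = people * mult
        displaced_cars = pd.Series(cars * mult, index=baseline["cell_id"].to_numpy())
        pred, _ = idp.predict_ratio(model, displaced_cars)
        assert pred.sum() == pytest.approx(displaced_people.sum(), rel=1e-9)


def _poisson_world(seed, n=500):
    rng = np.random.default_rng(seed)
    x = rng.gamma(2.0, 8.0, n)
    mu = np.exp(1.0 + 0.8 * np.log1p(x))
    y = rng.poisson(mu).astype(float)
    return _table(x, y), mu


def test_gam_flat_world_recovers_constant():
    """Constant people irrespective of cars: the smooth must stay flat.

    Per seed, the typical (median across cells) deviation of the fitted
    mean from the constant; the median over seeds must stay inside 1%.
    Tail cells can wiggle more when the automatic penalty undersmooths,
    so the extreme deviation is only loosely bounded."""
    typical, extreme = [], []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x = rng.gamma(2.0, 8.0, 500)
        y = rng.poisson(200.0, 500).astype(float)
        m = idp.fit_gam(_table(x, y))
        fitted = np.asarray(m.result.fittedvalues)
        rel = np.abs(fitted - 200.0) / 200.0
        typical.append(np.median(rel))
        extreme.append(rel.max())
    assert np.median(typical) < 0.01
    assert np.median(extreme) < 0.15


def test_gam_monotone_link_recovery():
    t, mu = _poisson_world(1)
    m = idp.fit_gam(t)
    fitted = np.asarray(m.result.fittedvalues)
    mare = np.mean(np.abs(fitted - mu) / mu)
    assert mare < 0.10
    # Poisson score equation with intercept reproduces the training total
    assert fitted.sum() == pytest.approx(t["people"].sum(), rel=0.005)
    assert m.deviance_explained > 0.5


def test_gam_refuses_tiny_tables():
    with pytest.raises(FitError):
        idp.fit_gam(_table([1.0] * 5, [2.0] * 5))


def test_gam_constant_x_falls_back_to_intercept():
    with pytest.warns(UserWarning, match="constant car counts"):
        m = idp.fit_gam(_table([3.0] * 20, list(np.arange(20.0) + 1)))
    assert m.degenerate
    pred = idp.predict_gam(m, pd.Series([3.0, 9.0], index=["a", "b"]))
    assert pred["predicted_people"]["a"] == pytest.approx(np.mean(np.arange(20.0) + 1), rel=1e-6)


def test_gam_prediction_positive_at_zero_and_flags_extrapolation():
    t, _ = _poisson_world(2)
    m = idp.fit_gam(t)
    pred = idp.predict_gam(m, pd.Series([0.0, 10.0 * m.x_max], index=["z", "big"]))
    assert pred["predicted_people"]["z"] > 0.0
    assert pred["out_of_range"]["big"]
    assert not pred["out_of_range"]["z"] or m.x_min > 0  # flagged only below support
    assert (pred["pred_low"] <= pred["predicted_people"]).all()
    assert (pred["predicted_people"] <= pred["pred_high"]).all()


def test_gam_interpolates_noiseless_monotone_world():
    x = np.linspace(1.0, 50.0, 200)
    y = np.exp(1.0 + 0.05 * x)
    m = idp.fit_gam(_table(x, y))
    probe = pd.Series(x[::20], index=[f"p{i}" for i in range(len(x[::20]))])
    pred = idp.predict_gam(m, probe)["predicted_people"].to_numpy()
    assert np.allclose(pred, np.exp(1.0 + 0.05 * probe.to_numpy()), rtol=0.02)


def test_population_change_levels_and_additivity():
    idx = ["c1", "c2", "c3"]
    baseline = pd.Series([5000.0, 3000.0, 2000.0], index=idx)
    ch = idp.population_change(baseline.copy(), baseline, "ratio", "k", (2022, 3))
    assert (ch["pct_change"].dropna() == 0).all()
    pred = pd.Series([600.0, 400.0, 200.0], index=idx)
    ch = idp.population_change(pred, baseline, "ratio", "k", (2022, 3))
    city = ch[ch["level"] == "city"].iloc[0]
    assert city["predicted_people"] == pytest.approx(pred.sum())
    assert city["pct_change"] == pytest.approx(-88.0)
    cells = ch[ch["level"] == "cell"]
    assert cells["predicted_people"].sum() == pytest.approx(city["predicted_people"])


def test_population_change_errors():
    idx = ["c1"]
    with pytest.raises(FitError):
        idp.population_change(pd.Series(dtype=float), pd.Series(dtype=float),
                              "ratio", "k", (2022, 3))
    with pytest.raises(ValueError):
        idp.population_change(pd.Series([1.0], index=["c1"]),
                              pd.Series([1.0], index=["c9"]), "ratio", "k", (2022, 3))


def test_estimate_city_end_to_end():
    rng = np.random.default_rng(6)
    cells = [f"c{i}" for i in range(30)]
    people = rng.gamma(2, 300, 30)
    cars = 0.05 * people
    grid = pd.DataFrame({"cell_id": cells, "baseline_people": people})
    rows = []
    for m in (4, 5):
        for c, x in zip(cells, cars):
            rows.append(("a", c, 2019, m, x, 1))
            rows.append(("a", c, 2022, m, 0.5 * x, 1))
    stats = _stats(rows)
    changes, summary = idp.estimate_city(stats, grid, 2019, [2020, 2022], city="a")
    city = changes[(changes["level"] == "city") & (changes["method"] == "ratio")]
    assert city["pct_change"].to_numpy() == pytest.approx([-50.0, -50.0], rel=1e-9)
    assert summary["matched_months"] == {2020: [], 2022: [4, 5]}
    gam_city = changes[(changes["level"] == "city") & (changes["method"] == "gam")]
    assert len(gam_city) == 2


def test_estimate_city_requires_matching_months():
    grid = pd.DataFrame({"cell_id": ["c1"] * 1, "baseline_people": [10.0]})
    stats = _stats([("a", "c1", 2019, 3, 1.0, 1), ("a", "c1", 2022, 9, 1.0, 1)])
    with pytest.raises(FitError, match="matching months"):
        idp.estimate_city(stats, grid, 2019, [2022], city="a")
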