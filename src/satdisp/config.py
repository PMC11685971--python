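"""Configuration objects for the synthetic world and the pipeline.

`WorldConfig` fully specifies a synthetic multi-city world: population
surfaces, the population->car link, the imaging process, false-positive
contamination, and the displacement scenario.  `RunConfig` holds the
pipeline thresholds; its defaults are the study constants (confidence
0.45, population coverage 50%, cloud drop 0.95, low-count flag 10,
cell-coverage rule 0.5, baseline year 2019, war cut date 2022-02-24).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigurationError


@dataclass
class PopModel:
    """Spatial population surface: Gaussian hotspots over a uniform floor."""

    hotspots_per_city: int = 3
    hotspot_sd_m: float = 700.0
    uniform_floor: float = 0.15  # share of people spread uniformly over the AOI

    def validate(self) -> None:
        if self.hotspots_per_city < 1:
            raise ConfigurationError("pop_model.hotspots_per_city", "must be >= 1")
        if self.hotspot_sd_m <= 0:
            raise ConfigurationError("pop_model.hotspot_sd_m", "must be > 0")
        if not 0.0 <= self.uniform_floor <= 1.0:
            raise ConfigurationError("pop_model.uniform_floor", "must be in [0, 1]")


@dataclass
class LinkModel:
    """Monotone link from cell population to expected visible cars.

    E[cars] = cars_per_person * people**exponent per fine cell, with
    Poisson count noise (or none).  `detection_rate` thins true cars into
    detector output; undetected cars remain in the ground-truth annotation
    set, so precision/recall sweeps are informative.  Scores are Beta
    draws: true cars skew high, false positives skew low.
    """

    cars_per_person: float = 0.05
    exponent: float = 1.0
    count_noise: str = "poisson"  # "poisson" | "none"
    detection_rate: float = 1.0
    true_score: tuple[float, float] = (8.0, 2.0)
    fp_score: tuple[float, float] = (2.0, 5.0)
    other_class_rate: float = 0.03  # non-"small car" detections per true car

    def validate(self) -> None:
        if self.cars_per_person < 0:
            raise ConfigurationError("link_model.cars_per_person", "must be >= 0")
        if self.exponent <= 0:
            raise ConfigurationError("link_model.exponent", "must be > 0")
        if self.count_noise not in ("poisson", "none"):
            raise ConfigurationError("link_model.count_noise", "must be 'poisson' or 'none'")
        if not 0.0 <= self.detection_rate <= 1.0:
            raise ConfigurationError("link_model.detection_rate", "must be in [0, 1]")
        for name, ab in (("true_score", self.true_score), ("fp_score", self.fp_score)):
            if len(ab) != 2 or min(ab) <= 0:
                raise ConfigurationError(f"link_model.{name}", "Beta parameters must be > 0")
        if self.other_class_rate < 0:
            raise ConfigurationError("link_model.other_class_rate", "must be >= 0")

    def expected_cars(self, people):
        import numpy as np

        return self.cars_per_person * np.power(np.asarray(people, dtype=float), self.exponent)


@dataclass
class ImageModel:
    """Per-month imaging process and metadata distributions."""

    mean_images_per_month: float = 2.5
    full_cover_prob: float = 0.4
    footprint_frac_range: tuple[float, float] = (0.3, 1.0)
    gsd_values: tuple[float, ...] = (0.3, 0.4, 0.5)
    gsd_probs: tuple[float, ...] = (0.35, 0.35, 0.30)
    off_nadir_range: tuple[float, float] = (5.0, 40.0)
    sun_elev_range: tuple[float, float] = (20.0, 60.0)
    cloud_zero_prob: float = 0.6
    cloud_beta: tuple[float, float] = (1.0, 4.0)
    full_cloud_prob: float = 0.05
    snow_months: tuple[int, ...] = (11, 12, 1, 2)
    snow_prob: float = 0.4
    snow_detect_factor: float = 0.5  # multiplicative car-detectability loss on snow

    def validate(self) -> None:
        if self.mean_images_per_month < 0:
            raise ConfigurationError("image_model.mean_images_per_month", "must be >= 0")
        if not 0.0 <= self.full_cover_prob <= 1.0:
            raise ConfigurationError("image_model.full_cover_prob", "must be in [0, 1]")
        lo, hi = self.footprint_frac_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("image_model.footprint_frac_range", "must be within (0, 1]")
        if len(self.gsd_values) != len(self.gsd_probs):
            raise ConfigurationError("image_model.gsd_probs", "length mismatch with gsd_values")
        if max(self.gsd_values) > 0.5:
            raise ConfigurationError("image_model.gsd_values", "GSD must be <= 0.5 m")
        if abs(sum(self.gsd_probs) - 1.0) > 1e-9:
            raise ConfigurationError("image_model.gsd_probs", "must sum to 1")
        for name, p in (
            ("cloud_zero_prob", self.cloud_zero_prob),
            ("full_cloud_prob", self.full_cloud_prob),
            ("snow_prob", self.snow_prob),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"image_model.{name}", "must be in [0, 1]")
        if not 0.0 <= self.snow_detect_factor <= 1.0:
            raise ConfigurationError("image_model.snow_detect_factor", "must be in [0, 1]")


@dataclass
class FPModel:
    """False-positive contamination inside exclusion polygons."""

    intensity_per_km2: float = 3.0
    margin_m: float = 5.0  # placement margin from polygon boundaries

    def validate(self) -> None:
        if self.intensity_per_km2 < 0:
            raise ConfigurationError("fp_model.intensity_per_km2", "must be >= 0")
        if self.margin_m < 0:
            raise ConfigurationError("fp_model.margin_m", "must be >= 0")


@dataclass
class Scenario:
    """Per-city multiplicative population change by year.

    `multipliers[year][aoi_id]` scales the baseline population surface.
    Cities absent from a year default to 1.0 (no change).
    """

    multipliers: dict = field(default_factory=dict)

    def validate(self) -> None:
        for year, per_city in self.multipliers.items():
            for aoi_id, m in per_city.items():
                if m < 0:
                    raise ConfigurationError(
                        "scenario.multipliers", f"negative multiplier {m} for {aoi_id} in {year}"
                    )

    def multiplier(self, year: int, aoi_id: str) -> float:
        return float(self.multipliers.get(year, {}).get(aoi_id, 1.0))


def _default_months() -> dict:
    return {2019: [3, 4, 5, 6, 7], 2020: [4, 5], 2022: [3, 4, 5, 6]}


def _default_scenario() -> Scenario:
    # East-to-west displacement in the war year: western cities receive
    # people, eastern cities lose them; a mild uniform dip in the COVID year.
    return Scenario(
        multipliers={
            2020: {"city_0": 0.95, "city_1": 0.95, "city_2": 0.95, "city_3": 0.95},
            2022: {"city_0": 1.5, "city_1": 1.3, "city_2": 0.6, "city_3": 0.35},
        }
    )


@dataclass
class WorldConfig:
    n_cities: int = 4
    aoi_size_km: float = 4.0
    pop_cell_m: float = 100.0
    city_populations: tuple[float, ...] | None = None  # default 25k each
    months: dict = field(default_factory=_default_months)
    baseline_year: int = 2019
    pop_model: PopModel = field(default_factory=PopModel)
    link_model: LinkModel = field(default_factory=LinkModel)
    image_model: ImageModel = field(default_factory=ImageModel)
    fp_model: FPModel = field(default_factory=FPModel)
    scenario: Scenario = field(default_factory=_default_scenario)
    aoi_gap_m: float = 10_000.0
    aoi_origin_offset_m: float = 300.0  # misaligns AOIs from the 1 km lattice
    seed: int = 0

    def validate(self) -> None:
        if self.n_cities < 1:
            raise ConfigurationError("n_cities", "must be >= 1")
        if self.aoi_size_km <= 0:
            raise ConfigurationError("aoi_size_km", "must be > 0")
        if self.pop_cell_m <= 0:
            raise ConfigurationError("pop_cell_m", "must be > 0")
        aoi_m = self.aoi_size_km * 1000.0
        if abs(aoi_m / self.pop_cell_m - round(aoi_m / self.pop_cell_m)) > 1e-9:
            raise ConfigurationError("aoi_size_km", "AOI side must be a multiple of pop_cell_m")
        if self.city_populations is not None:
            if len(self.city_populations) != self.n_cities:
                raise ConfigurationError("city_populations", "length must equal n_cities")
            if min(self.city_populations) < 0:
                raise ConfigurationError("city_populations", "must be >= 0")
        if self.baseline_year not in self.months:
            raise ConfigurationError("months", "baseline_year must have at least one month")
        for year, ms in self.months.items():
            if any(m < 1 or m > 12 for m in ms):
                raise ConfigurationError("months", f"invalid month list for {year}")
        if self.seed < 0:
            raise ConfigurationError("seed", "must be >= 0")
        self.pop_model.validate()
        self.link_model.validate()
        self.image_model.validate()
        self.fp_model.validate()
        self.scenario.validate()

    @property
    def aoi_size_m(self) -> float:
        return self.aoi_size_km * 1000.0

    def city_ids(self) -> list[str]:
        return [f"city_{i}" for i in range(self.n_cities)]

    def populations(self) -> list[float]:
        if self.city_populations is not None:
            return list(self.city_populations)
        return [25_000.0] * self.n_cities


@dataclass
class RunConfig:
    """Pipeline thresholds; defaults are the study constants."""

    confidence_threshold: float = 0.45
    tune_beta: float = 0.5
    tune_step: float = 0.05
    match_dist_m: float = 2.5
    min_pop_coverage_pct: float = 50.0
    cloud_drop: float = 0.95
    cloud_review: float = 0.5
    low_count_flag: int = 10
    min_area_pct: float = 1.0
    cell_size_m: float = 1000.0
    cell_coverage_frac: float = 0.5
    baseline_year: int = 2019
    comparison_years: tuple[int, ...] = (2020, 2022)
    cut_date: str = "2022-02-24"
    methods: tuple[str, ...] = ("ratio", "gam")
    gam_basis_dim: int = 10
    gam_min_cells: int = 10
    r2_report_threshold: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ConfigurationError("confidence_threshold", "must be in [0, 1]")
        if self.tune_beta <= 0:
            raise ConfigurationError("tune_beta", "must be > 0")
        if not 0.0 < self.tune_step < 1.0:
            raise ConfigurationError("tune_step", "must be in (0, 1)")
        if not 0.0 <= self.min_pop_coverage_pct <= 100.0:
            raise ConfigurationError("min_pop_coverage_pct", "must be in [0, 100]")
        if not 0.0 <= self.cloud_drop <= 1.0:
            raise ConfigurationError("cloud_drop", "must be in [0, 1]")
        if self.low_count_flag < 0:
            raise ConfigurationError("low_count_flag", "must be >= 0")
        if not 0.0 < self.cell_coverage_frac <= 1.0:
            raise ConfigurationError("cell_coverage_frac", "must be in (0, 1]")
        for m in self.methods:
            if m not in ("ratio", "gam"):
                raise ConfigurationError("methods", f"unknown method '{m}'")


def _to_plain(obj):
    if isinstance(obj, (WorldConfig, RunConfig, PopModel, LinkModel, ImageModel, FPModel, Scenario)):
        return {k: _to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(cfg, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=True))


def _tupled(d: dict, keys: Sequence[str]) -> dict:
    return {k: tuple(v) if k in keys and v is not None else v for k, v in d.items()}


def load_world_config(path: str | Path) -> "WorldConfig":
    raw = yaml.safe_load(Path(path).read_text())
    raw["pop_model"] = PopModel(**raw.get("pop_model", {}))
    lm = _tupled(raw.get("link_model", {}), ["true_score", "fp_score"])
    raw["link_model"] = LinkModel(**lm)
    im = _tupled(
        raw.get("image_model", {}),
        ["footprint_frac_range", "gsd_values", "gsd_probs", "off_nadir_range",
         "sun_elev_range", "cloud_beta", "snow_months"],
    )
    raw["image_model"] = ImageModel(**im)
    raw["fp_model"] = FPModel(**raw.get("fp_model", {}))
    sc = raw.get("scenario", {})
    raw["scenario"] = Scenario(
        multipliers={int(y): dict(v) for y, v in sc.get("multipliers", {}).items()}
    )
    raw["months"] = {int(y): list(v) for y, v in raw.get("months", {}).items()}
    if raw.get("city_populations") is not None:
        raw["city_populations"] = tuple(raw["city_populations"])
    cfg = WorldConfig(**raw)
    cfg.validate()
    return cfg


def load_run_config(path: str | Path) -> "RunConfig":
    raw = yaml.safe_load(Path(path).read_text())
    raw = _tupled(raw, ["comparison_years", "methods"])
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
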