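"""Synthetic multi-city daily pollutant panels with known planted structure.

Cities are scattered in clusters around continental centroids; each belongs to
a group controlling its baseline level and linear trend per pollutant. Daily
values follow

    baseline + trend * years_elapsed + amp * cos(2*pi*(month - phase)/12) + noise

truncated at zero, with a configurable fraction of days dropped (missingness)
and a fraction replaced by gross outliers in (1000, 2000] ug/m3 so QC can find
all of them. Every planted parameter is recorded in a truth ledger for
downstream recovery tests. The seasonal phase flips by six months in the
southern hemisphere.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SyntheticConfig",
    "ConfigError",
    "generate_city_metadata",
    "generate_daily_series",
    "generate_emissions",
    "write_dataset",
    "DEFAULT_GROUP_WEIGHTS",
]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


# group -> (baseline_pm, baseline_o3, trend_pm, trend_o3), ug/m3 and ug/m3/yr
_DEFAULT_BASELINE_PM = {"hotspot": 85.0, "delhi_like": 160.0, "pm_dominant": 48.0,
                        "o3_rising": 20.0, "clean": 14.0}
_DEFAULT_BASELINE_O3 = {"hotspot": 135.0, "delhi_like": 140.0, "pm_dominant": 72.0,
                        "o3_rising": 112.0, "clean": 62.0}
_DEFAULT_TREND_PM = {"hotspot": -6.0, "delhi_like": -10.0, "pm_dominant": -4.0,
                     "o3_rising": 1.5, "clean": -0.8}
_DEFAULT_TREND_O3 = {"hotspot": -5.0, "delhi_like": 8.0, "pm_dominant": -2.0,
                     "o3_rising": 6.0, "clean": -0.5}
DEFAULT_GROUP_WEIGHTS = {"hotspot": 0.40, "delhi_like": 0.05, "pm_dominant": 0.27,
                         "o3_rising": 0.05, "clean": 0.23}

# (country, continent, lon, lat, development, dominant group, weight)
_CENTROIDS = (
    ("China", "Asia", 112.0, 33.0, "developing", "hotspot", 0.30),
    ("India", "Asia", 78.0, 23.0, "developing", "hotspot", 0.17),
    ("Germany", "Europe", 10.0, 49.0, "developed", "pm_dominant", 0.23),
    ("USA", "North America", -95.0, 39.0, "developed", "clean", 0.18),
    ("Chile", "South America", -66.0, -27.0, "developing", "hotspot", 0.07),
    ("Australia", "Oceania", 149.0, -31.0, "developed", "clean", 0.03),
    ("South Africa", "Africa", 25.0, -8.0, "developing", "pm_dominant", 0.02),
)

_EARTH_KM_PER_DEG = 111.2


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; same config (incl. seed) => identical output."""

    n_cities: int = 120
    start_date: str = "2019-01-01"
    end_date: str = "2022-12-31"
    seed: int = 0
    baseline_pm: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINE_PM))
    baseline_o3: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_BASELINE_O3))
    trend_pm: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TREND_PM))
    trend_o3: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_TREND_O3))
    group_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS))
    seasonal_amp_pm: float = 12.0
    seasonal_amp_o3: float = 15.0
    seasonal_phase_pm: float = 1.0  # month of the northern PM2.5 peak (winter)
    seasonal_phase_o3: float = 7.0  # month of the northern O3 peak (summer)
    noise_sd: float = 10.0
    # kept small by default so a typical city-year still meets the 360-valid-day
    # quota; raise freely when exercising the QC path itself
    missing_rate: float = 0.002
    outlier_rate: float = 0.001
    spatial_corr_range: float = 900.0  # km scatter of cities around their centroid
    population_range: tuple[float, float] = (5e5, 2.5e7)
    emission_coupling: float = 30.0  # tons/yr of emissions per ug/m3 of planted mean
    emission_noise_sd: float = 300.0

    def validate(self) -> None:
        if self.n_cities < 2:
            raise ConfigError(f"n_cities must be >= 2, got {self.n_cities}")
        start = pd.Timestamp(self.start_date)
        end = pd.Timestamp(self.end_date)
        if end <= start:
            raise ConfigError("end_date must be after start_date")
        if self.missing_rate + self.outlier_rate >= 1:
            raise ConfigError("missing_rate + outlier_rate must be < 1")
        if not 0 <= self.missing_rate <= 1 or not 0 <= self.outlier_rate <= 1:
            raise ConfigError("rates must be fractions in [0, 1]")
        for name in ("seasonal_amp_pm", "seasonal_amp_o3", "noise_sd", "emission_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.emission_coupling < 0:
            raise ConfigError("emission_coupling must be >= 0")
        groups = set(self.group_weights)
        for name in ("baseline_pm", "baseline_o3", "trend_pm", "trend_o3"):
            if set(getattr(self, name)) != groups:
                raise ConfigError(f"{name} must cover exactly the groups in group_weights")
        if self.population_range[0] <= 0 or self.population_range[1] < self.population_range[0]:
            raise ConfigError("population_range must be positive and ordered")


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def generate_city_metadata(cfg: SyntheticConfig) -> pd.DataFrame:
    """City table: id, name, country, continent, coordinates, population,
    development class and planted group.

    Coordinates cluster around a few continental centroids so city attributes
    are genuinely spatially autocorrelated. At least one "delhi_like" city is
    planted whenever that group is configured with positive weight.
    """
    cfg.validate()
    rng = _rng(cfg, 0)
    n = cfg.n_cities
    weights = np.array([c[6] for c in _CENTROIDS])
    cluster_idx = rng.choice(len(_CENTROIDS), size=n, p=weights / weights.sum())

    groups = list(cfg.group_weights)
    gw = np.array([cfg.group_weights[g] for g in groups], dtype=float)
    gw = gw / gw.sum()

    sigma_deg = cfg.spatial_corr_range / _EARTH_KM_PER_DEG
    rows = []
    for i in range(n):
        country, continent, lon0, lat0, dev, dominant, _ = _CENTROIDS[cluster_idx[i]]
        lat = float(np.clip(lat0 + rng.normal(0, sigma_deg / 2), -89.0, 89.0))
        lon = lon0 + rng.normal(0, sigma_deg / max(np.cos(np.radians(lat0)), 0.2) / 2)
        lon = float((lon + 180.0) % 360.0 - 180.0)
        if dominant in groups and rng.random() < 0.8:
            group = dominant
        else:
            group = groups[rng.choice(len(groups), p=gw)]
        lo, hi = cfg.population_range
        population = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        rows.append({"city_id": f"C{i:03d}", "name": f"City{i:03d}", "country": country,
                     "continent": continent, "longitude": lon, "latitude": lat,
                     "population": population, "development": dev, "group": group})
    meta = pd.DataFrame(rows)
    if "delhi_like" in groups and cfg.group_weights["delhi_like"] > 0 \
            and not (meta["group"] == "delhi_like").any():
        meta.loc[meta.index[0], "group"] = "delhi_like"
    return meta


def _deterministic_signal(cfg: SyntheticConfig, dates: pd.DatetimeIndex, group: str,
                          southern: bool, pollutant: str) -> np.ndarray:
    if pollutant == "PM25":
        baseline, trend = cfg.baseline_pm[group], cfg.trend_pm[group]
        amp, phase = cfg.seasonal_amp_pm, cfg.seasonal_phase_pm
    else:
        baseline, trend = cfg.baseline_o3[group], cfg.trend_o3[group]
        amp, phase = cfg.seasonal_amp_o3, cfg.seasonal_phase_o3
    if southern:
        phase = (phase + 6.0) % 12.0
    t0 = dates[0]
    years = np.asarray((dates - t0).days, dtype=float) / 365.25
    seasonal = amp * np.cos(2 * np.pi * (np.asarray(dates.month, dtype=float) - phase) / 12.0)
    return np.asarray(baseline + trend * years + seasonal, dtype=float)


def generate_daily_series(cfg: SyntheticConfig,
                          metadata: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Daily long-format panel plus the planted-parameter truth ledger.

    The ledger records, per city and pollutant, the planted baseline, trend
    (and its sign), the deterministic annual means per calendar year and their
    study-period mean — enough to recover every downstream label exactly on
    noise-free data.
    """
    cfg.validate()
    rng = _rng(cfg, 1)
    dates = pd.date_range(cfg.start_date, cfg.end_date, freq="D")
    years = sorted(set(dates.year))

    frames = []
    truth_cities: dict = {}
    for row in metadata.itertuples():
        southern = row.latitude < 0
        city_truth = {"group": row.group, "latitude": row.latitude}
        for pollutant in ("PM25", "O3"):
            det = _deterministic_signal(cfg, dates, row.group, southern, pollutant)
            noise = rng.normal(0.0, cfg.noise_sd, size=det.size) if cfg.noise_sd > 0 \
                else np.zeros(det.size)
            value = np.maximum(det + noise, 0.0)
            keep = rng.random(det.size) >= cfg.missing_rate
            outlier = rng.random(det.size) < cfg.outlier_rate
            # outliers drawn in (1000, 2000]: strictly beyond the QC threshold
            value = np.where(outlier, 2000.0 - rng.random(det.size) * 1000.0, value)
            frames.append(pd.DataFrame({
                "city_id": row.city_id,
                "date": dates[keep],
                "pollutant": pollutant,
                "value": value[keep],
            }))
            annual = {}
            for y in years:
                mask = dates.year == y
                annual[int(y)] = float(np.maximum(det[mask], 0.0).mean())
            trend = (cfg.trend_pm if pollutant == "PM25" else cfg.trend_o3)[row.group]
            city_truth[pollutant] = {
                "baseline": (cfg.baseline_pm if pollutant == "PM25"
                             else cfg.baseline_o3)[row.group],
                "trend": trend,
                "trend_sign": int(np.sign(trend)),
                "annual_means": annual,
                "study_mean": float(np.mean(list(annual.values()))),
            }
        truth_cities[row.city_id] = city_truth

    series = pd.concat(frames, ignore_index=True)
    truth = {
        "seed": cfg.seed,
        "start_date": cfg.start_date,
        "end_date": cfg.end_date,
        "years": [int(y) for y in years],
        "group_weights": dict(cfg.group_weights),
        "cities": truth_cities,
    }
    return series, truth


def generate_emissions(metadata: pd.DataFrame, cfg: SyntheticConfig, truth: dict) -> pd.DataFrame:
    """Annual NOx/VOC emission table (tons/yr) coupled to planted city means.

    NOx couples to the planted PM2.5 study mean and VOC to the planted O3
    study mean with slope ``emission_coupling``; both are nonnegative.
    """
    cfg.validate()
    rng = _rng(cfg, 2)
    rows = []
    for row in metadata.itertuples():
        pm_mean = truth["cities"][row.city_id]["PM25"]["study_mean"]
        o3_mean = truth["cities"][row.city_id]["O3"]["study_mean"]
        nox = 100.0 + cfg.emission_coupling * pm_mean + rng.normal(0, cfg.emission_noise_sd)
        voc = 80.0 + cfg.emission_coupling * o3_mean + rng.normal(0, cfg.emission_noise_sd)
        rows.append({"city_id": row.city_id, "nox_tons": max(nox, 0.0),
                     "voc_tons": max(voc, 0.0)})
    return pd.DataFrame(rows)


def write_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict:
    """Generate and write series.csv, cities.csv, emissions.csv and truth.json.

    Returns the truth ledger. Output is byte-identical for identical configs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metadata = generate_city_metadata(cfg)
    series, truth = generate_daily_series(cfg, metadata)
    emissions = generate_emissions(metadata, cfg, truth)
    out = series.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(outdir / "series.csv", index=False)
    metadata.to_csv(outdir / "cities.csv", index=False)
    emissions.to_csv(outdir / "emissions.csv", index=False)
    truth["config"] = {k: (dict(v) if isinstance(v, Mapping) else v)
                       for k, v in dataclasses.asdict(cfg).items()}
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return truth
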