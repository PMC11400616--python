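"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the vectorized code paths of the package: the
Mann-Kendall oracle loops over pairs and counts tied groups with a Counter,
the Moran oracle evaluates the dense double sum, and the weighted-Pearson
oracle applies the covariance formula term by term.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from copollute import synthetic_data as sd


# ---------------------------------------------------------------- oracles


def mk_s_oracle(x) -> int:
    s = 0
    n = len(x)
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = float(x[j]) - float(x[i])
            s += int(d > 0) - int(d < 0)
    return s


def mk_var_oracle(x) -> float:
    n = len(x)
    tie_term = 0.0
    for q in Counter(x).values():
        if q > 1:
            tie_term += q * (q - 1) * (2 * q + 5)
    return (n * (n - 1) * (2 * n + 5) - tie_term) / 18.0


def global_bimoran_oracle(x, y, dense_w) -> float:
    """(1/n) * sum_i sum_j w_ij zx_i zy_j on population-standardized values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    zx = (x - x.mean()) / x.std()
    zy = (y - y.mean()) / y.std()
    n = len(x)
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += dense_w[i, j] * zx[i] * zy[j]
    return total / n


def weighted_pearson_oracle(x, y, w) -> float:
    wsum = sum(w)
    mx = sum(wi * xi for wi, xi in zip(w, x)) / wsum
    my = sum(wi * yi for wi, yi in zip(w, y)) / wsum
    cov = sum(wi * (xi - mx) * (yi - my) for wi, xi, yi in zip(w, x, y)) / wsum
    vx = sum(wi * (xi - mx) ** 2 for wi, xi in zip(w, x)) / wsum
    vy = sum(wi * (yi - my) ** 2 for wi, yi in zip(w, y)) / wsum
    return cov / math.sqrt(vx * vy)


def mda8_oracle(hourly, prev_tail=None):
    """Enumerate all 24 windows ending at an hour of the day."""
    tail = [float("nan")] * 7
    if prev_tail is not None:
        vals = list(prev_tail)
        tail[7 - len(vals):] = vals
    arr = tail + list(hourly) + [float("nan")] * (24 - len(hourly))
    best, n_comp = None, 0
    for end in range(24):
        window = arr[end: end + 8]
        finite = [v for v in window if not math.isnan(v)]
        if len(finite) >= 6:
            n_comp += 1
            mean = sum(finite) / len(finite)
            best = mean if best is None else max(best, mean)
    return best, n_comp


# ---------------------------------------------------------------- fixtures


def make_two_group_config(**overrides) -> sd.SyntheticConfig:
    """Two custom groups with equal weight; group names are deliberately not
    continental defaults so assignment follows the weights exactly."""
    params = dict(
        n_cities=120,
        seed=11,
        group_weights={"dirty_half": 0.5, "tidy_half": 0.5},
        baseline_pm={"dirty_half": 70.0, "tidy_half": 15.0},
        baseline_o3={"dirty_half": 130.0, "tidy_half": 60.0},
        trend_pm={"dirty_half": -5.0, "tidy_half": -1.0},
        trend_o3={"dirty_half": -4.0, "tidy_half": -1.0},
    )
    params.update(overrides)
    return sd.SyntheticConfig(**params)


@pytest.fixture(scope="session")
def default_cfg() -> sd.SyntheticConfig:
    return sd.SyntheticConfig(n_cities=30, seed=5)


@pytest.fixture(scope="session")
def default_dataset(default_cfg):
    metadata = sd.generate_city_metadata(default_cfg)
    series, truth = sd.generate_daily_series(default_cfg, metadata)
    emissions = sd.generate_emissions(metadata, default_cfg, truth)
    return metadata, series, truth, emissions


@pytest.fixture()
def toy_series() -> pd.DataFrame:
    """One city, one pollutant, a 30-day month of constant value 10."""
    dates = pd.date_range("2020-04-01", periods=30, freq="D")
    return pd.DataFrame({
        "city_id": "C000", "date": dates, "pollutant": "PM25",
        "value": 10.0, "valid": True,
    })
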