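"""Spatial association between city-level pollutant fields.

Spatial weights are k-nearest-neighbor under great-circle distance,
row-standardized. The bivariate local Moran statistic at site i is
``c * x_i * sum_j w_ij y_j`` on standardized variables (c = 1); the global
statistic is the mean of the local ones. Pseudo-significance uses conditional
permutation: x_i stays fixed while y is permuted over the other sites.
A geographically weighted local Pearson correlation (bisquare kernel,
adaptive bandwidth) summarizes per-city PM2.5-O3 coupling, and a quadratic
fit describes how that correlation varies with the PM2.5 level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpatialWeights",
    "BiMoran",
    "great_circle_km",
    "build_weights",
    "bimoran",
    "local_correlation",
    "temporal_correlation",
    "correlation_curvature",
    "precursor_association",
]

_EARTH_RADIUS_KM = 6371.0


def great_circle_km(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    """Pairwise haversine distance matrix in km."""
    lat = np.radians(np.asarray(lat, dtype=float))
    lon = np.radians(np.asarray(lon, dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = np.sin(dlat / 2) ** 2 + np.cos(lat[:, None]) * np.cos(lat[None, :]) * np.sin(dlon / 2) ** 2
    return 2 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass(frozen=True)
class SpatialWeights:
    """Row-standardized kNN weights: w_ii = 0, each row sums to 1."""

    city_ids: tuple
    neighbors: np.ndarray  # (n, k) int indices
    weights: np.ndarray  # (n, k) floats, each row sums to 1
    k: int

    def to_dense(self) -> np.ndarray:
        n = len(self.city_ids)
        W = np.zeros((n, n))
        for i in range(n):
            W[i, self.neighbors[i]] = self.weights[i]
        return W

    def lag(self, y: np.ndarray) -> np.ndarray:
        """Spatial lag: row-weighted average of y over each site's neighbors."""
        y = np.asarray(y, dtype=float)
        return (self.weights * y[self.neighbors]).sum(axis=1)


def build_weights(metadata: pd.DataFrame, k: int = 5) -> SpatialWeights:
    """kNN graph over city coordinates, ties broken by (distance, city order)."""
    n = len(metadata)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cities, got {n}")
    lat = metadata["latitude"].to_numpy(dtype=float)
    lon = metadata["longitude"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("coordinates must be finite")
    dist = great_circle_km(lat, lon)
    np.fill_diagonal(dist, np.inf)
    order = np.arange(n)
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        # lexsort: distance first, then stable city order for deterministic ties
        idx = np.lexsort((order, dist[i]))
        neighbors[i] = idx[:k]
        if np.any(dist[i, neighbors[i]] == 0):
            logger.warning("duplicate coordinates near city %s; kNN ties resolved by id order",
                           metadata["city_id"].iloc[i])
    weights = np.full((n, k), 1.0 / k)
    return SpatialWeights(city_ids=tuple(metadata["city_id"]), neighbors=neighbors,
                          weights=weights, k=k)


def _standardize(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} must be finite")
    sd = v.std()  # population sd (divisor n)
    if sd == 0:
        raise ValueError(f"{name} has zero variance; standardization undefined")
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class BiMoran:
    """Global and local bivariate Moran's I with permutation pseudo-p."""

    global_i: float
    global_pseudo_p: float
    local_i: np.ndarray
    quadrant: tuple  # HH / LL / LH / HL per city
    pseudo_p: np.ndarray
    n_perm: int
    seed: int
    c: float = 1.0


def _pseudo_p(observed: float, perms: np.ndarray, alternative: str) -> float:
    m = perms.size
    if alternative == "greater":
        extreme = int((perms >= observed).sum())
    elif alternative == "less":
        extreme = int((perms <= observed).sum())
    elif alternative == "sign":
        if observed >= 0:
            extreme = int((perms >= observed).sum())
        else:
            extreme = int((perms <= observed).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + extreme) / (m + 1)


def bimoran(x, y, W: SpatialWeights, n_perm: int = 999, seed: int = 0, *,
            c: float = 1.0, alternative: str = "sign") -> BiMoran:
    """Bivariate Moran statistics of x against the spatial lag of y.

    Both variables are standardized to zero mean and unit (population)
    variance. ``alternative`` controls the permutation p-value: "sign"
    (default, one-sided on the observed sign of the statistic), "greater" or
    "less".
    """
    n = len(W.city_ids)
    zx = _standardize(x, "x")
    zy = _standardize(y, "y")
    if zx.size != n or zy.size != n:
        raise ValueError("x and y must match the weight matrix city set")

    lag = W.lag(zy)
    local = c * zx * lag
    global_i = float(local.mean())
    quadrant = tuple(
        ("H" if zx[i] >= 0 else "L") + ("H" if lag[i] >= 0 else "L") for i in range(n)
    )

    rng = np.random.default_rng(seed)
    k = W.k
    pseudo = np.empty(n)
    for i in range(n):
        pool = np.delete(zy, i)
        # sample k neighbor values without replacement, n_perm times
        pick = rng.random((n_perm, n - 1)).argsort(axis=1)[:, :k]
        perm_lag = (pool[pick] * W.weights[i]).sum(axis=1)
        pseudo[i] = _pseudo_p(local[i], c * zx[i] * perm_lag, alternative)

    perm_global = np.empty(n_perm)
    for p in range(n_perm):
        zperm = rng.permutation(zy)
        perm_global[p] = float((c * zx * W.lag(zperm)).mean())
    global_p = _pseudo_p(global_i, perm_global, alternative)

    return BiMoran(global_i=global_i, global_pseudo_p=global_p, local_i=local,
                   quadrant=quadrant, pseudo_p=pseudo, n_perm=n_perm, seed=seed, c=c)


def _kernel_weights(dist_row: np.ndarray, bandwidth: int | None, kernel: str) -> np.ndarray:
    if bandwidth is None or kernel == "uniform":
        return np.ones_like(dist_row)
    if kernel != "bisquare":
        raise ValueError(f"unknown kernel {kernel!r}")
    others = np.sort(dist_row[dist_row > 0])
    if bandwidth > others.size:
        bandwidth = others.size
    d_b = others[bandwidth - 1]
    if d_b == 0:
        return (dist_row == 0).astype(float)
    w = (1 - (dist_row / d_b) ** 2) ** 2
    w[dist_row >= d_b] = 0.0
    w[dist_row == 0] = 1.0
    return w


def _weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    if vx == 0 or vy == 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


def local_correlation(pm_panel: pd.DataFrame, o3_panel: pd.DataFrame,
                      metadata: pd.DataFrame, *, bandwidth: int | None = 15,
                      kernel: str = "bisquare") -> pd.DataFrame:
    """Geographically weighted local Pearson correlation of PM2.5 vs O3.

    ``pm_panel`` and ``o3_panel`` are wide tables (rows = city_id, columns =
    periods, e.g. annual means); rows must align with ``metadata``. Every city
    pools its own and its kernel-weighted neighbors' period pairs; with a
    uniform kernel covering all cities each local value equals the pooled
    global Pearson r. Cities with fewer than 3 effective pairs get NaN.
    """
    ids = list(metadata["city_id"])
    pm = pm_panel.reindex(ids)
    o3 = o3_panel.reindex(ids)
    dist = great_circle_km(metadata["latitude"].to_numpy(), metadata["longitude"].to_numpy())
    rows = []
    for i, city in enumerate(ids):
        kw = _kernel_weights(dist[i], bandwidth, kernel)
        xs, ys, ws = [], [], []
        for j in np.nonzero(kw > 0)[0]:
            paired = pd.concat({"pm": pm.iloc[j], "o3": o3.iloc[j]}, axis=1).dropna()
            if len(paired) == 0:
                continue
            xs.append(paired["pm"].to_numpy(dtype=float))
            ys.append(paired["o3"].to_numpy(dtype=float))
            ws.append(np.full(len(paired), kw[j]))
        n_pairs = sum(len(v) for v in xs)
        if n_pairs < 3:
            logger.info("local correlation undefined for %s (%d pairs)", city, n_pairs)
            r = np.nan
        else:
            r = _weighted_pearson(np.concatenate(xs), np.concatenate(ys), np.concatenate(ws))
        rows.append({"city_id": city, "local_r": r, "n_pairs": int(n_pairs),
                     "bandwidth": -1 if bandwidth is None else bandwidth, "kernel": kernel})
    return pd.DataFrame(rows)


def temporal_correlation(series: pd.DataFrame) -> pd.DataFrame:
    """Per-city Pearson correlation of daily PM2.5 vs daily O3 (alternative
    reading of the per-city correlation surface)."""
    valid = series[series["valid"]]
    wide = valid.pivot_table(index=["city_id", "date"], columns="pollutant",
                             values="value", aggfunc="first").dropna()
    rows = []
    for city, grp in wide.groupby(level="city_id"):
        r = np.nan
        if len(grp) >= 3 and grp["PM25"].std() > 0 and grp["O3"].std() > 0:
            r = float(np.corrcoef(grp["PM25"], grp["O3"])[0, 1])
        rows.append({"city_id": city, "local_r": r, "n_pairs": int(len(grp))})
    return pd.DataFrame(rows)


def correlation_curvature(local_r, pm_means) -> dict:
    """OLS of local_r on (pm, pm^2): coefficients, R^2 and the fitted peak.

    The peak location -b/(2a) is reported only when curvature is negative.
    """
    r = np.asarray(local_r, dtype=float)
    pm = np.asarray(pm_means, dtype=float)
    mask = np.isfinite(r) & np.isfinite(pm)
    r, pm = r[mask], pm[mask]
    if r.size < 4:
        raise ValueError(f"need at least 4 cities with defined local_r, got {r.size}")
    if np.ptp(pm) == 0:
        raise ValueError("singular design: all PM2.5 means equal")
    X = np.column_stack([np.ones_like(pm), pm, pm ** 2])
    beta, *_ = np.linalg.lstsq(X, r, rcond=None)
    fitted = X @ beta
    sst = float(((r - r.mean()) ** 2).sum())
    ssr = float(((r - fitted) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - ssr / sst
    a = float(beta[2])
    peak = None
    peak_value = None
    # numerically-zero curvature (e.g. exactly linear data) reports no peak
    tol = 1e-10 * max(1.0, float(np.max(np.abs(r)))) / max(1.0, float(np.ptp(pm))) ** 2
    if a < -tol:
        peak = float(-beta[1] / (2 * a))
        peak_value = float(beta[0] + beta[1] * peak + a * peak ** 2)
    return {"intercept": float(beta[0]), "linear": float(beta[1]), "quadratic": a,
            "r2": r2, "peak_pm": peak, "peak_correlation": peak_value,
            "n": int(r.size)}


def precursor_association(emissions: np.ndarray, concentration_means: np.ndarray,
                          W: SpatialWeights, n_perm: int = 999, seed: int = 0) -> dict:
    """Bivariate Moran and plain Pearson r of emissions vs concentrations
    (pure delegation to :func:`bimoran`)."""
    result = bimoran(emissions, concentration_means, W, n_perm=n_perm, seed=seed)
    r = float(np.corrcoef(np.asarray(emissions, float),
                          np.asarray(concentration_means, float))[0, 1])
    return {"bimoran": result, "pearson_r": r}
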