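"""Six-type exposure-risk typology per pollutant, paired across pollutants.

Three concentration bands (extremely high / high / low) crossed with the trend
direction (increasing / decreasing) give six labels: HR, ST, R, DST, S, HS.
Band edges, written with strict inequalities on both sides in the source
scheme, are closed into the middle band. The combined label is always
"<PM2.5 label> + <O3 label>".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "BANDS",
    "RISK_LABELS",
    "BAND_EDGES",
    "RiskLabel",
    "band",
    "risk_label",
    "combine",
    "label_cities",
    "population_by_risk",
]

EXTREMELY_HIGH = "extremely_high"
HIGH = "high"
LOW = "low"
BANDS = (EXTREMELY_HIGH, HIGH, LOW)

RISK_LABELS = ("HR", "ST", "R", "DST", "S", "HS")

#: (low edge, high edge) of the middle band per pollutant, ug/m3.
BAND_EDGES = {"PM25": (25.0, 35.0), "O3": (100.0, 120.0)}

_LABEL_MAP = {
    (EXTREMELY_HIGH, "increasing"): "HR",
    (EXTREMELY_HIGH, "decreasing"): "ST",
    (HIGH, "increasing"): "R",
    (HIGH, "decreasing"): "DST",
    (LOW, "increasing"): "S",
    (LOW, "decreasing"): "HS",
}


@dataclass(frozen=True)
class RiskLabel:
    city_id: str
    pollutant: str
    band: str
    direction: str
    label: str
    flat: bool  # true when the trend was exactly flat (Z = 0)


def band(pollutant: str, period_mean: float, *, edges: dict | None = None) -> str:
    """Concentration band for a valid period mean.

    PM2.5: >35 extremely high, [25, 35] high, <25 low.
    O3:    >120 extremely high, [100, 120] high, <100 low.
    """
    edges = BAND_EDGES if edges is None else edges
    if pollutant not in edges:
        raise ValueError(f"unknown pollutant {pollutant!r}")
    if not np.isfinite(period_mean) or period_mean < 0:
        raise ValueError(f"period mean must be finite and nonnegative, got {period_mean}")
    lo, hi = edges[pollutant]
    if period_mean > hi:
        return EXTREMELY_HIGH
    if period_mean >= lo:
        return HIGH
    return LOW


def risk_label(band_: str, direction: str) -> str:
    """Map (band, direction) to one of the six labels."""
    key = (band_, direction)
    if key not in _LABEL_MAP:
        raise ValueError(f"no label for band={band_!r}, direction={direction!r}")
    return _LABEL_MAP[key]


def combine(pm_label: str, o3_label: str) -> str:
    """Ordered pair label; the PM2.5 label always comes first."""
    return f"{pm_label} + {o3_label}"


def label_cities(period_means: pd.DataFrame, directions: pd.DataFrame, *,
                 edges: dict | None = None) -> pd.DataFrame:
    """Per-city, per-pollutant risk labels plus the combined pair.

    ``period_means``: (city_id, pollutant, mean, is_valid); ``directions``:
    (city_id, pollutant, direction) with direction in {increasing, decreasing,
    none}. A flat trend (direction "none") is mapped to the decreasing side
    with ``flat=True`` — the six-cell scheme has no neutral cell. Returns a
    table with one row per (city, pollutant) plus a ``combined`` column filled
    on PM25 rows for dually labeled cities.
    """
    means = period_means[period_means["is_valid"]][["city_id", "pollutant", "mean"]]
    merged = means.merge(directions[["city_id", "pollutant", "direction"]],
                         on=["city_id", "pollutant"], how="inner")
    rows = []
    for _, r in merged.iterrows():
        flat = r["direction"] == "none"
        direction = "decreasing" if flat else r["direction"]
        b = band(r["pollutant"], r["mean"], edges=edges)
        rows.append(RiskLabel(city_id=r["city_id"], pollutant=r["pollutant"], band=b,
                              direction=direction, label=risk_label(b, direction), flat=flat))
    out = pd.DataFrame(rows, columns=[f.name for f in RiskLabel.__dataclass_fields__.values()])
    if len(out) == 0:
        out["combined"] = pd.Series(dtype=object)
        return out
    pm = out[out["pollutant"] == "PM25"].set_index("city_id")["label"]
    o3 = out[out["pollutant"] == "O3"].set_index("city_id")["label"]
    both = pm.index.intersection(o3.index)
    combined = {c: combine(pm[c], o3[c]) for c in both}
    out["combined"] = [
        combined.get(r.city_id) if r.pollutant == "PM25" else None for r in out.itertuples()
    ]
    return out


def population_by_risk(labels: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Population totals per combined label, split by continent and development
    class when those columns exist in ``metadata``.

    Cities without a population entry are excluded and logged. Totals conserve
    the grand population of labeled cities.
    """
    combined = labels.dropna(subset=["combined"])[["city_id", "combined"]]
    cols = ["city_id", "population"]
    for extra in ("continent", "development"):
        if extra in metadata.columns:
            cols.append(extra)
    merged = combined.merge(metadata[cols], on="city_id", how="left")
    missing = merged["population"].isna()
    if missing.any():
        logger.info("population_by_risk excluded %d cities without population", int(missing.sum()))
        merged = merged[~missing]
    group_cols = ["combined"] + [c for c in ("continent", "development") if c in merged.columns]
    out = (merged.groupby(group_cols, as_index=False)["population"].sum()
           .rename(columns={"population": "population_total"}))
    return out.sort_values(group_cols).reset_index(drop=True)
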