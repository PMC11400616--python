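"""Dominant-pollution typing of cities from period-mean PM2.5 and O3.

Four labels partition the concentration plane at 35 ug/m3 (PM2.5) and
100 ug/m3 (O3): compound (P-O), PM2.5-dominated, O3-dominated, and Clean.
Boundary equality goes to the lower-severity side because the exceedance rule
is strict on the high side.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "classify",
    "classify_table",
    "type_shares",
    "type_transitions",
    "exceedance_fraction_label",
]

P_O = "P-O"
PM25_DOMINATED = "PM25_dominated"
O3_DOMINATED = "O3_dominated"
CLEAN = "Clean"
LABELS = (P_O, PM25_DOMINATED, O3_DOMINATED, CLEAN)

PM_THRESHOLD = 35.0
O3_THRESHOLD = 100.0


def classify(pm_mean: float, o3_mean: float, *, pm_threshold: float = PM_THRESHOLD,
             o3_threshold: float = O3_THRESHOLD) -> str:
    """Label one (pm_mean, o3_mean) pair. Both means must be finite and >= 0."""
    if not (np.isfinite(pm_mean) and np.isfinite(o3_mean)):
        raise ValueError("means must be finite")
    if pm_mean < 0 or o3_mean < 0:
        raise ValueError("concentrations are nonnegative")
    pm_high = pm_mean > pm_threshold
    o3_high = o3_mean > o3_threshold
    if pm_high and o3_high:
        return P_O
    if pm_high:
        return PM25_DOMINATED
    if o3_high:
        return O3_DOMINATED
    return CLEAN


def classify_table(aggregates: pd.DataFrame, *, pm_threshold: float = PM_THRESHOLD,
                   o3_threshold: float = O3_THRESHOLD) -> pd.DataFrame:
    """Label each (city, period) with valid means for both pollutants.

    ``aggregates`` is long-format with columns (city_id, pollutant, period_key,
    mean, is_valid). Cities missing a valid mean for either pollutant in a
    period are excluded; the exclusion count is logged.
    """
    valid = aggregates[aggregates["is_valid"]]
    wide = valid.pivot_table(index=["city_id", "period_key"], columns="pollutant",
                             values="mean", aggfunc="first").reset_index()
    total = wide.shape[0]
    if "PM25" not in wide.columns or "O3" not in wide.columns:
        logger.info("typing excluded all %d rows: a pollutant is entirely missing", total)
        return pd.DataFrame(columns=["city_id", "period_key", "label", "pm_mean", "o3_mean"])
    wide = wide.dropna(subset=["PM25", "O3"])
    if len(wide) < total:
        logger.info("typing excluded %d city-periods lacking a valid pair", total - len(wide))
    wide["label"] = [
        classify(pm, o3, pm_threshold=pm_threshold, o3_threshold=o3_threshold)
        for pm, o3 in zip(wide["PM25"], wide["O3"])
    ]
    out = wide.rename(columns={"PM25": "pm_mean", "O3": "o3_mean"})
    return out[["city_id", "period_key", "label", "pm_mean", "o3_mean"]].reset_index(drop=True)


def exceedance_fraction_label(daily_pm: pd.Series, daily_o3: pd.Series, *,
                              fraction: float = 0.5,
                              pm_threshold: float = PM_THRESHOLD,
                              o3_threshold: float = O3_THRESHOLD) -> str:
    """Alternative day-counting mode: label each day, call the period P-O if at
    least ``fraction`` of paired days are P-O days, and analogously for the
    single-pollutant labels (ties broken toward the more severe label)."""
    paired = pd.concat({"pm": daily_pm, "o3": daily_o3}, axis=1).dropna()
    if len(paired) == 0:
        raise ValueError("no paired days")
    day_labels = [
        classify(pm, o3, pm_threshold=pm_threshold, o3_threshold=o3_threshold)
        for pm, o3 in zip(paired["pm"], paired["o3"])
    ]
    counts = pd.Series(day_labels).value_counts()
    for label in (P_O, PM25_DOMINATED, O3_DOMINATED):
        if counts.get(label, 0) / len(paired) >= fraction:
            return label
    return CLEAN


def type_shares(labels: pd.Series | pd.DataFrame) -> pd.Series:
    """Fraction of labeled cities per type; fractions sum to 1."""
    if isinstance(labels, pd.DataFrame):
        labels = labels["label"]
    if len(labels) == 0:
        raise ValueError("no labeled cities")
    shares = labels.value_counts(normalize=True)
    return shares.reindex(LABELS, fill_value=0.0)


def type_transitions(yearly_labels: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """First-year to last-year transitions per city.

    ``yearly_labels`` has columns (city_id, period_key, label) with period_key
    an integer year. Returns (per-city table, 4x4 count matrix with rows =
    first-year label, columns = last-year label). Cities with fewer than two
    labeled years are excluded and logged.
    """
    rows = []
    excluded = 0
    for city_id, grp in yearly_labels.groupby("city_id", sort=True):
        grp = grp.sort_values("period_key")
        if len(grp) < 2:
            excluded += 1
            continue
        rows.append({
            "city_id": city_id,
            "first_year": int(grp["period_key"].iloc[0]),
            "first_label": grp["label"].iloc[0],
            "last_year": int(grp["period_key"].iloc[-1]),
            "last_label": grp["label"].iloc[-1],
        })
    if excluded:
        logger.info("transitions excluded %d cities with a single labeled year", excluded)
    per_city = pd.DataFrame(rows, columns=["city_id", "first_year", "first_label",
                                           "last_year", "last_label"])
    matrix = pd.DataFrame(0, index=list(LABELS), columns=list(LABELS), dtype=int)
    for _, r in per_city.iterrows():
        matrix.loc[r["first_label"], r["last_label"]] += 1
    return per_city, matrix
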