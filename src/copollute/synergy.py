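"""Four-quadrant synergy classification of endpoint-year concentration change.

Each city's relative rate of change (ROC = end-year mean / start-year mean) is
computed per pollutant and the pair is thresholded at 1 to yield one of four
quadrants: both up, both down, or the two discordant "seesaw" cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SynergyResult",
    "QUADRANTS",
    "roc",
    "synergy_quadrant",
    "classify_cities",
    "synergy_summary",
]

SYNERGISTIC_INCREASE = "SynergisticIncrease"
SYNERGISTIC_DECREASE = "SynergisticDecrease"
PM_UP_O3_DOWN = "PM_up_O3_down"
PM_DOWN_O3_UP = "PM_down_O3_up"
QUADRANTS = (SYNERGISTIC_INCREASE, SYNERGISTIC_DECREASE, PM_UP_O3_DOWN, PM_DOWN_O3_UP)


@dataclass(frozen=True)
class SynergyResult:
    city_id: str
    roc_pm: float
    roc_o3: float
    quadrant: str
    pct_change_pm: float
    pct_change_o3: float


def roc(c_start: float, c_end: float) -> float:
    """Relative rate of change, end-year over start-year mean."""
    if not np.isfinite(c_start) or not np.isfinite(c_end):
        raise ValueError("annual means must be finite")
    if c_start <= 0:
        raise ValueError(f"start-year mean must be positive, got {c_start}")
    if c_end < 0:
        raise ValueError(f"end-year mean must be nonnegative, got {c_end}")
    return c_end / c_start


def synergy_quadrant(roc_pm: float, roc_o3: float) -> str:
    """Quadrant label; a ratio of exactly 1 counts as an increase."""
    if roc_pm >= 1 and roc_o3 >= 1:
        return SYNERGISTIC_INCREASE
    if roc_pm < 1 and roc_o3 < 1:
        return SYNERGISTIC_DECREASE
    if roc_pm >= 1:
        return PM_UP_O3_DOWN
    return PM_DOWN_O3_UP


def classify_cities(annual_means: pd.DataFrame, start_year: int, end_year: int) -> pd.DataFrame:
    """Classify every city with valid endpoint-year means for both pollutants.

    ``annual_means`` is a long table with columns (city_id, pollutant, year,
    mean, is_valid). Cities lacking a valid positive start-year mean for either
    pollutant are excluded and logged.
    """
    valid = annual_means[annual_means["is_valid"]]
    wide = valid.pivot_table(
        index="city_id", columns=["pollutant", "year"], values="mean", aggfunc="first"
    )
    rows = []
    excluded = 0
    for city_id, row in wide.iterrows():
        try:
            pm0, pm1 = row[("PM25", start_year)], row[("PM25", end_year)]
            o30, o31 = row[("O3", start_year)], row[("O3", end_year)]
        except KeyError:
            excluded += 1
            continue
        if any(not np.isfinite(v) for v in (pm0, pm1, o30, o31)) or pm0 <= 0 or o30 <= 0:
            excluded += 1
            continue
        roc_pm, roc_o3 = roc(pm0, pm1), roc(o30, o31)
        rows.append(
            SynergyResult(
                city_id=city_id,
                roc_pm=roc_pm,
                roc_o3=roc_o3,
                quadrant=synergy_quadrant(roc_pm, roc_o3),
                pct_change_pm=(roc_pm - 1.0) * 100.0,
                pct_change_o3=(roc_o3 - 1.0) * 100.0,
            )
        )
    if excluded:
        logger.info("synergy classification excluded %d cities with invalid endpoint years", excluded)
    return pd.DataFrame(rows, columns=[f.name for f in SynergyResult.__dataclass_fields__.values()])


def synergy_summary(results: pd.DataFrame, metadata: pd.DataFrame | None = None) -> dict:
    """Quadrant shares and within-quadrant mean percent changes.

    Shares sum to 1 over classified cities. If ``metadata`` with a ``country``
    column is given, a quadrant-by-country cross-tab is included.
    """
    if len(results) == 0:
        raise ValueError("no classified cities to summarize")
    n = len(results)
    summary: dict = {"n_cities": int(n), "shares": {}, "mean_pct_change": {}, "counts": {}}
    for quad in QUADRANTS:
        sub = results[results["quadrant"] == quad]
        summary["counts"][quad] = int(len(sub))
        summary["shares"][quad] = len(sub) / n
        if len(sub):
            summary["mean_pct_change"][quad] = {
                "PM25": float(sub["pct_change_pm"].mean()),
                "O3": float(sub["pct_change_o3"].mean()),
            }
    if metadata is not None and "country" in metadata.columns:
        merged = results.merge(metadata[["city_id", "country"]], on="city_id", how="left")
        tab = pd.crosstab(merged["quadrant"], merged["country"])
        summary["by_country"] = {q: tab.loc[q].to_dict() for q in tab.index}
    return summary
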