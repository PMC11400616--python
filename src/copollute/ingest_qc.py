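"""Reading, quality control and aggregation of daily city pollutant series.

QC flags (never alters) implausible records: concentrations above 999 ug/m3,
negative or non-finite values. Aggregates carry validity quotas — a monthly
mean needs at least 27 valid days, an annual mean at least 360 — and invalid
aggregates are kept with ``is_valid=False``, never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "QCReport",
    "qc_filter",
    "mda8",
    "aggregate",
    "season_of",
    "MONTHLY_QUOTA",
    "ANNUAL_QUOTA",
    "QC_MAX_VALUE",
]

POLLUTANTS = ("PM25", "O3")

QC_MAX_VALUE = 999.0  # values strictly above are discarded
MONTHLY_QUOTA = 27  # minimum valid days for a monthly mean
ANNUAL_QUOTA = 360  # minimum valid days for an annual mean

_SEASON_BLOCKS = {12: "DJF", 1: "DJF", 2: "DJF", 3: "MAM", 4: "MAM", 5: "MAM",
                  6: "JJA", 7: "JJA", 8: "JJA", 9: "SON", 10: "SON", 11: "SON"}
_NORTH_NAMES = {"DJF": "winter", "MAM": "spring", "JJA": "summer", "SON": "autumn"}
_SOUTH_NAMES = {"DJF": "summer", "MAM": "autumn", "JJA": "winter", "SON": "spring"}


@dataclass
class QCReport:
    """Row accounting for one QC pass; input rows reconcile with output rows
    plus dropped rows."""

    n_input: int = 0
    n_dropped_unparseable: int = 0
    n_flagged_above_max: int = 0
    n_flagged_negative: int = 0
    n_flagged_nonfinite: int = 0
    n_duplicates_collapsed: int = 0
    n_output: int = 0
    row_errors: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = ["QC report", "---------"]
        for name in ("n_input", "n_dropped_unparseable", "n_flagged_above_max",
                     "n_flagged_negative", "n_flagged_nonfinite",
                     "n_duplicates_collapsed", "n_output"):
            lines.append(f"{name}: {getattr(self, name)}")
        for err in self.row_errors[:50]:
            lines.append(f"row error: {err}")
        return "\n".join(lines) + "\n"


def qc_filter(raw: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Validate and flag a raw long-format table (city_id, date, pollutant,
    value).

    Returns one record per (city, pollutant, date) with a ``valid`` flag.
    Unparseable dates, unknown pollutant codes and non-numeric values are
    row-level errors: the row is dropped and the error recorded. Duplicate
    (city, pollutant, date) rows collapse to the mean of their valid values.
    """
    report = QCReport(n_input=len(raw))
    df = raw.copy()
    df["value"] = pd.to_numeric(df["value"], errors="coerce")
    parsed_dates = pd.to_datetime(df["date"], errors="coerce", format="mixed")

    bad_date = parsed_dates.isna()
    bad_pollutant = ~df["pollutant"].isin(POLLUTANTS)
    for idx in df.index[bad_date]:
        report.row_errors.append({"row": int(idx), "error": "unparseable date",
                                  "value": str(raw.loc[idx, "date"])})
    for idx in df.index[bad_pollutant & ~bad_date]:
        report.row_errors.append({"row": int(idx), "error": "unknown pollutant",
                                  "value": str(raw.loc[idx, "pollutant"])})
    drop = bad_date | bad_pollutant
    report.n_dropped_unparseable = int(drop.sum())
    df = df[~drop].copy()
    df["date"] = parsed_dates[~drop].dt.normalize()

    value = df["value"].to_numpy(dtype=float)
    nonfinite = ~np.isfinite(value)
    negative = np.isfinite(value) & (value < 0)
    above = np.isfinite(value) & (value > QC_MAX_VALUE)
    report.n_flagged_nonfinite = int(nonfinite.sum())
    report.n_flagged_negative = int(negative.sum())
    report.n_flagged_above_max = int(above.sum())
    df["valid"] = ~(nonfinite | negative | above)

    key = ["city_id", "pollutant", "date"]
    if df.duplicated(key).any():
        n_before = len(df)

        def _collapse(grp: pd.DataFrame) -> pd.Series:
            valid = grp[grp["valid"]]
            if len(valid):
                return pd.Series({"value": valid["value"].mean(), "valid": True})
            return pd.Series({"value": grp["value"].iloc[0], "valid": False})

        df = (df.groupby(key, sort=True)[["value", "valid"]]
              .apply(_collapse).reset_index())
        report.n_duplicates_collapsed = n_before - len(df)
        logger.warning("collapsed %d duplicate (city, pollutant, date) rows by mean",
                       report.n_duplicates_collapsed)
    df = df.sort_values(key).reset_index(drop=True)
    df["valid"] = df["valid"].astype(bool)
    report.n_output = len(df)
    return df[key + ["value", "valid"]], report


def mda8(hourly, prev_tail=None, *, min_valid_hours: int = 6,
         min_windows: int = 18) -> tuple[float, bool]:
    """Maximum 8-hour rolling-average O3 for one city-day.

    ``hourly`` holds up to 24 hourly values for the calendar day (NaN =
    missing); ``prev_tail`` optionally holds the last 7 hours of the previous
    day, used by windows that reach back across midnight. Each of the 24
    windows ends at one hour of the day and needs at least 6 of its 8 hours
    valid; the day value is the maximum window mean and the day is valid only
    if at least 18 windows were computable.
    """
    hourly = np.asarray(hourly, dtype=float)
    if hourly.size == 0:
        return np.nan, False
    if hourly.size > 24:
        raise ValueError(f"at most 24 hourly values per day, got {hourly.size}")
    day = np.full(24, np.nan)
    day[: hourly.size] = hourly
    tail = np.full(7, np.nan)
    if prev_tail is not None:
        prev_tail = np.asarray(prev_tail, dtype=float)
        if prev_tail.size > 7:
            raise ValueError("prev_tail holds at most the prior day's last 7 hours")
        tail[7 - prev_tail.size:] = prev_tail
    arr = np.concatenate([tail, day])  # index h+7 is day hour h

    best = -np.inf
    n_computable = 0
    for h in range(24):
        window = arr[h: h + 8]
        finite = np.isfinite(window)
        if finite.sum() >= min_valid_hours:
            n_computable += 1
            best = max(best, float(window[finite].mean()))
    if n_computable == 0:
        return np.nan, False
    return best, n_computable >= min_windows


def season_of(month: int, southern: bool = False) -> str:
    """Meteorological season name for a month, hemisphere-aware."""
    block = _SEASON_BLOCKS[month]
    return (_SOUTH_NAMES if southern else _NORTH_NAMES)[block]


def _season_year(dates: pd.Series) -> pd.Series:
    # December counts toward the following year's DJF block
    return dates.dt.year + (dates.dt.month == 12).astype(int)


def _monthly(series: pd.DataFrame, quota: int) -> pd.DataFrame:
    df = series.copy()
    df["year"] = df["date"].dt.year
    df["month"] = df["date"].dt.month
    valid = df[df["valid"]]
    grp = valid.groupby(["city_id", "pollutant", "year", "month"])["value"]
    out = grp.agg(mean="mean", n_valid_days="count").reset_index()
    # carry months that exist only as invalid records
    all_months = (df.groupby(["city_id", "pollutant", "year", "month"])
                  .size().reset_index()[["city_id", "pollutant", "year", "month"]])
    out = all_months.merge(out, on=["city_id", "pollutant", "year", "month"], how="left")
    out["n_valid_days"] = out["n_valid_days"].fillna(0).astype(int)
    out["is_valid"] = out["n_valid_days"] >= quota
    return out


def aggregate(series: pd.DataFrame, period: str, *, metadata: pd.DataFrame | None = None,
              northern_calendar: bool = False, monthly_quota: int = MONTHLY_QUOTA,
              annual_quota: int = ANNUAL_QUOTA,
              study_years: tuple[int, int] | None = None) -> pd.DataFrame:
    """Aggregate a QC-filtered series to one of ``month``, ``season``, ``year``
    or ``study-period`` means with validity accounting.

    Monthly means are valid with >= ``monthly_quota`` valid days, annual means
    with >= ``annual_quota`` valid days; a seasonal mean is valid only when all
    three member months are valid; the study-period mean is the mean of valid
    annual means and is valid only when every study year is valid. Season
    labels are hemisphere-aware via the metadata latitude unless
    ``northern_calendar`` forces northern labels.

    Returns columns (city_id, pollutant, period, period_key, mean,
    n_valid_days, is_valid) plus a ``year`` column for year-based periods.
    """
    if period not in ("month", "season", "year", "study-period"):
        raise ValueError(f"unknown period {period!r}")
    monthly = _monthly(series, monthly_quota)

    if period == "month":
        out = monthly.copy()
        out["period_key"] = (out["year"].astype(str) + "-"
                             + out["month"].astype(str).str.zfill(2))
        out["period"] = "month"
        return out[["city_id", "pollutant", "period", "period_key", "year",
                    "mean", "n_valid_days", "is_valid"]]

    if period == "season":
        df = monthly.copy()
        dates = pd.to_datetime(dict(year=df["year"], month=df["month"], day=1))
        df["season_year"] = _season_year(dates)
        df["block"] = df["month"].map(_SEASON_BLOCKS)
        southern = set()
        if metadata is not None and not northern_calendar and "latitude" in metadata.columns:
            southern = set(metadata.loc[metadata["latitude"] < 0, "city_id"])
        rows = []
        for (city, pol, syear, block), grp in df.groupby(
                ["city_id", "pollutant", "season_year", "block"]):
            n_days = int(grp["n_valid_days"].sum())
            ok = len(grp) == 3 and bool(grp["is_valid"].all())
            mean = np.nan
            if n_days > 0:
                weights = grp["n_valid_days"].to_numpy(dtype=float)
                means = grp["mean"].to_numpy(dtype=float)
                mask = weights > 0
                mean = float(np.average(means[mask], weights=weights[mask]))
            name = season_of({"DJF": 1, "MAM": 4, "JJA": 7, "SON": 10}[block],
                             southern=city in southern)
            rows.append({"city_id": city, "pollutant": pol, "period": "season",
                         "period_key": f"{syear}-{name}", "year": syear,
                         "mean": mean, "n_valid_days": n_days, "is_valid": ok})
        return pd.DataFrame(rows)

    valid = series[series["valid"]].copy()
    valid["year"] = valid["date"].dt.year
    grp = valid.groupby(["city_id", "pollutant", "year"])["value"]
    annual = grp.agg(mean="mean", n_valid_days="count").reset_index()
    all_years = series.copy()
    all_years["year"] = all_years["date"].dt.year
    frame = (all_years.groupby(["city_id", "pollutant", "year"]).size()
             .reset_index()[["city_id", "pollutant", "year"]])
    annual = frame.merge(annual, on=["city_id", "pollutant", "year"], how="left")
    annual["n_valid_days"] = annual["n_valid_days"].fillna(0).astype(int)
    annual["is_valid"] = annual["n_valid_days"] >= annual_quota

    if period == "year":
        out = annual.copy()
        out["period"] = "year"
        out["period_key"] = out["year"].astype(str)
        return out[["city_id", "pollutant", "period", "period_key", "year",
                    "mean", "n_valid_days", "is_valid"]]

    # study-period
    if study_years is None:
        years = sorted(series["date"].dt.year.unique())
    else:
        years = list(range(study_years[0], study_years[1] + 1))
    rows = []
    for (city, pol), grp in annual.groupby(["city_id", "pollutant"]):
        grp = grp.set_index("year")
        ok = all(y in grp.index and bool(grp.loc[y, "is_valid"]) for y in years)
        valid_means = grp.loc[grp["is_valid"], "mean"]
        mean = float(valid_means.mean()) if len(valid_means) else np.nan
        rows.append({"city_id": city, "pollutant": pol, "period": "study-period",
                     "period_key": f"{years[0]}-{years[-1]}" if years else "",
                     "year": years[-1] if years else np.nan, "mean": mean,
                     "n_valid_days": int(grp["n_valid_days"].sum()), "is_valid": ok})
    return pd.DataFrame(rows)
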