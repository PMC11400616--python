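import numpy as np
import pandas as pd
import pytest

from copollute import ingest_qc
from conftest import mda8_oracle


def raw_row(date="2020-01-01", value=10.0, pollutant="PM25", city="C000"):
    return {"city_id": city, "date": date, "pollutant": pollutant, "value": value}


class TestQCFilter:
    def test_above_threshold_invalid(self):
        df, report = ingest_qc.qc_filter(pd.DataFrame([raw_row(value=1000.0)]))
        assert not df["valid"].iloc[0]
        assert report.n_flagged_above_max == 1

    def test_at_threshold_valid(self):
        df, _ = ingest_qc.qc_filter(pd.DataFrame([raw_row(value=999.0)]))
        assert df["valid"].iloc[0]

    def test_negative_invalid(self):
        df, report = ingest_qc.qc_filter(pd.DataFrame([raw_row(value=-3.0)]))
        assert not df["valid"].iloc[0]
        assert report.n_flagged_negative == 1

    def test_nonfinite_invalid(self):
        df, report = ingest_qc.qc_filter(pd.DataFrame([raw_row(value=np.nan)]))
        assert not df["valid"].iloc[0]
        assert report.n_flagged_nonfinite == 1

    def test_qc_never_alters_valid_values(self):
        values = [0.0, 12.5, 999.0, 500.0]
        df, _ = ingest_qc.qc_filter(pd.DataFrame(
            [raw_row(date=f"2020-01-{d:02d}", value=v) for d, v in enumerate(values, 1)]))
        assert df["valid"].all()
        assert sorted(df["value"]) == sorted(values)

    def test_unknown_pollutant_dropped(self):
        df, report = ingest_qc.qc_filter(pd.DataFrame(
            [raw_row(), raw_row(pollutant="NO2")]))
        assert len(df) == 1
        assert report.n_dropped_unparseable == 1
        assert any("unknown pollutant" in e["error"] for e in report.row_errors)

    def test_unparseable_date_dropped(self):
        df, report = ingest_qc.qc_filter(pd.DataFrame(
            [raw_row(), raw_row(date="not-a-date")]))
        assert len(df) == 1
        assert any("unparseable date" in e["error"] for e in report.row_errors)

    def test_duplicates_collapse_to_mean_of_valid(self):
        df, report = ingest_qc.qc_filter(pd.DataFrame([
            raw_row(value=10.0), raw_row(value=20.0), raw_row(value=5000.0)]))
        assert len(df) == 1
        assert df["value"].iloc[0] == pytest.approx(15.0)
        assert df["valid"].iloc[0]
        assert report.n_duplicates_collapsed == 2

    def test_duplicates_all_invalid(self):
        df, _ = ingest_qc.qc_filter(pd.DataFrame(
            [raw_row(value=-1.0), raw_row(value=2000.0)]))
        assert len(df) == 1
        assert not df["valid"].iloc[0]

    def test_row_accounting_reconciles(self, default_dataset):
        _, series, _, _ = default_dataset
        raw = series.copy()
        raw["date"] = raw["date"].dt.strftime("%Y-%m-%d")
        df, report = ingest_qc.qc_filter(raw)
        assert report.n_input == len(raw)
        assert report.n_output + report.n_dropped_unparseable \
            + report.n_duplicates_collapsed == report.n_input
        # one record per key
        assert not df.duplicated(["city_id", "pollutant", "date"]).any()

    def test_report_text(self):
        _, report = ingest_qc.qc_filter(pd.DataFrame([raw_row(value=1000.0)]))
        text = report.to_text()
        assert "n_flagged_above_max: 1" in text


class TestMDA8:
    def test_monotone_ramp(self):
        value, valid = ingest_qc.mda8(list(range(1, 25)))
        assert value == pytest.approx(20.5)
        assert valid

    def test_constant_series(self):
        value, valid = ingest_qc.mda8([80.0] * 24)
        assert value == pytest.approx(80.0)
        assert valid

    def test_empty_block_invalid(self):
        value, valid = ingest_qc.mda8([])
        assert not valid
        assert np.isnan(value)

    def test_mostly_missing_invalid(self):
        hourly = [np.nan] * 20 + [50.0] * 4
        _, valid = ingest_qc.mda8(hourly)
        assert not valid

    def test_prev_tail_used(self):
        # huge values in the prior evening lift early-morning windows
        value, _ = ingest_qc.mda8([10.0] * 24, prev_tail=[200.0] * 7)
        oracle, _ = mda8_oracle([10.0] * 24, [200.0] * 7)
        assert value == pytest.approx(oracle)
        assert value > 10.0

    def test_random_profiles_match_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            hourly = rng.uniform(0, 150, size=24)
            drop = rng.random(24) < 0.2
            hourly[drop] = np.nan
            tail = rng.uniform(0, 150, size=7) if rng.random() < 0.5 else None
            value, valid = ingest_qc.mda8(hourly, tail)
            exp_value, exp_windows = mda8_oracle(list(hourly), None if tail is None else list(tail))
            if exp_value is None:
                assert np.isnan(value)
            else:
                assert value == pytest.approx(exp_value)
            assert valid == (exp_windows >= 18)

    def test_bounded_by_max_hour(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            hourly = rng.uniform(0, 100, size=24)
            value, _ = ingest_qc.mda8(hourly)
            assert value <= hourly.max() + 1e-12


class TestAggregate:
    def _month(self, n_days, value=10.0, year=2020, month=1, valid=True):
        dates = pd.date_range(f"{year}-{month:02d}-01", periods=n_days, freq="D")
        return pd.DataFrame({"city_id": "C000", "date": dates, "pollutant": "PM25",
                             "value": value, "valid": valid})

    def test_month_26_days_invalid(self):
        out = ingest_qc.aggregate(self._month(26), "month")
        assert not out["is_valid"].iloc[0]

    def test_month_27_days_valid(self):
        out = ingest_qc.aggregate(self._month(27), "month")
        assert out["is_valid"].iloc[0]

    def test_month_mean_value(self):
        out = ingest_qc.aggregate(self._month(30, value=10.0), "month")
        assert out["mean"].iloc[0] == pytest.approx(10.0)
        assert out["is_valid"].iloc[0]
        assert out["n_valid_days"].iloc[0] == 30

    def test_year_360_days_valid(self):
        dates = pd.date_range("2021-01-01", periods=360, freq="D")
        series = pd.DataFrame({"city_id": "C000", "date": dates, "pollutant": "O3",
                               "value": 50.0, "valid": True})
        out = ingest_qc.aggregate(series, "year")
        assert out["is_valid"].iloc[0]
        assert out["mean"].iloc[0] == pytest.approx(50.0)

    def test_year_359_days_invalid(self):
        dates = pd.date_range("2021-01-01", periods=359, freq="D")
        series = pd.DataFrame({"city_id": "C000", "date": dates, "pollutant": "O3",
                               "value": 50.0, "valid": True})
        out = ingest_qc.aggregate(series, "year")
        assert not out["is_valid"].iloc[0]

    def test_invalid_days_not_counted(self):
        series = self._month(31)
        series.loc[series.index[:5], "valid"] = False
        out = ingest_qc.aggregate(series, "month")
        assert out["n_valid_days"].iloc[0] == 26
        assert not out["is_valid"].iloc[0]

    def test_mean_preserving_on_constant(self):
        dates = pd.date_range("2020-01-01", "2021-12-31", freq="D")
        series = pd.DataFrame({"city_id": "C000", "date": dates, "pollutant": "PM25",
                               "value": 42.0, "valid": True})
        for period in ("month", "season", "year", "study-period"):
            out = ingest_qc.aggregate(series, period)
            valid = out[out["is_valid"]]
            assert len(valid) > 0
            assert np.allclose(valid["mean"], 42.0)

    def test_season_needs_three_valid_months(self):
        # JJA with only July and August present
        frames = [self._month(31, month=7), self._month(31, month=8)]
        out = ingest_qc.aggregate(pd.concat(frames), "season")
        jja = out[out["period_key"].str.contains("summer")]
        assert len(jja) == 1 and not jja["is_valid"].iloc[0]

    def test_december_rolls_to_next_year_winter(self):
        frames = [self._month(31, year=2020, month=12),
                  self._month(31, year=2021, month=1),
                  self._month(28, year=2021, month=2)]
        out = ingest_qc.aggregate(pd.concat(frames), "season")
        winter = out[out["is_valid"]]
        assert len(winter) == 1
        assert winter["period_key"].iloc[0] == "2021-winter"

    def test_southern_hemisphere_labels(self):
        frames = [self._month(31, year=2020, month=12),
                  self._month(31, year=2021, month=1),
                  self._month(28, year=2021, month=2)]
        meta = pd.DataFrame({"city_id": ["C000"], "latitude": [-33.0], "longitude": [151.0]})
        out = ingest_qc.aggregate(pd.concat(frames), "season", metadata=meta)
        valid = out[out["is_valid"]]
        assert valid["period_key"].iloc[0] == "2021-summer"
        # forcing northern labels restores winter
        out_n = ingest_qc.aggregate(pd.concat(frames), "season", metadata=meta,
                                    northern_calendar=True)
        assert out_n[out_n["is_valid"]]["period_key"].iloc[0] == "2021-winter"

    def test_study_period_requires_all_years(self):
        y1 = pd.DataFrame({"city_id": "C000",
                           "date": pd.date_range("2020-01-01", "2020-12-31", freq="D"),
                           "pollutant": "PM25", "value": 10.0, "valid": True})
        y2 = pd.DataFrame({"city_id": "C000",
                           "date": pd.date_range("2021-01-01", "2021-06-30", freq="D"),
                           "pollutant": "PM25", "value": 20.0, "valid": True})
        out = ingest_qc.aggregate(pd.concat([y1, y2]), "study-period")
        assert not out["is_valid"].iloc[0]
        # mean still reported over the valid years, flagged invalid
        assert out["mean"].iloc[0] == pytest.approx(10.0)

    def test_study_period_mean_of_annual_means(self):
        frames = []
        for year, value in ((2020, 10.0), (2021, 30.0)):
            frames.append(pd.DataFrame({
                "city_id": "C000",
                "date": pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D"),
                "pollutant": "PM25", "value": value, "valid": True}))
        out = ingest_qc.aggregate(pd.concat(frames), "study-period")
        assert out["is_valid"].iloc[0]
        assert out["mean"].iloc[0] == pytest.approx(20.0)

    def test_unknown_period_rejected(self, toy_series):
        with pytest.raises(ValueError):
            ingest_qc.aggregate(toy_series, "decade")

    def test_empty_series_yields_invalid(self, toy_series):
        sub = toy_series.copy()
        sub["valid"] = False
        out = ingest_qc.aggregate(sub, "month")
        assert not out["is_valid"].any()


def test_season_of():
    assert ingest_qc.season_of(1) == "winter"
    assert ingest_qc.season_of(7) == "summer"
    assert ingest_qc.season_of(1, southern=True) == "summer"
    assert ingest_qc.season_of(7, southern=True) == "winter"
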