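import numpy as np
import pandas as pd
import pytest

from windmatch import (SyntheticConfig, add_lags_and_leads, aggregate_hourly_to_daily,
                       assign_treatment, evaluate_imputation, generate_dataset,
                       impute_missing, inject_missingness, read_daily_dataset,
                       write_daily_dataset)
from windmatch.datasets import lag_name, parse_lag_name


class TestAggregateHourlyToDaily:
    def test_too_many_missing_hours_gives_missing_day(self):
        values = [10.0] * 20 + [np.nan] * 4
        assert np.isnan(aggregate_hourly_to_daily(values))
        # exactly 3 missing is still tolerated
        assert aggregate_hourly_to_daily([10.0] * 21 + [np.nan] * 3) == 10.0

    def test_constant_series(self):
        assert aggregate_hourly_to_daily([10.0] * 96) == 10.0

    def test_trimmed_mean_drops_each_tail(self):
        # 96 values, floor(96 * 0.025) = 2 dropped per tail -> mean of 3..94
        assert aggregate_hourly_to_daily(np.arange(1.0, 97.0)) == pytest.approx(48.5)

    def test_zero_trim_equals_plain_mean(self):
        rng = np.random.default_rng(3)
        v = rng.uniform(0, 50, 24)
        assert aggregate_hourly_to_daily(v, trim_frac=0.0) == pytest.approx(v.mean())

    def test_result_within_input_range(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            v = rng.uniform(0, 80, int(rng.integers(5, 100)))
            out = aggregate_hourly_to_daily(v, trim_frac=0.1)
            assert v.min() <= out <= v.max()

    def test_all_missing_is_missing_not_error(self):
        assert np.isnan(aggregate_hourly_to_daily([np.nan] * 24, max_missing=30))

    @pytest.mark.parametrize("bad", [[], None])
    def test_empty_input_rejected(self, bad):
        with pytest.raises((ValueError, TypeError)):
            aggregate_hourly_to_daily(bad if bad is not None else np.array([]))

    def test_bad_trim_frac_rejected(self):
        with pytest.raises(ValueError):
            aggregate_hourly_to_daily([1.0, 2.0], trim_frac=0.6)


class TestAssignTreatment:
    @pytest.mark.parametrize("deg,expected", [
        (45.0, 1), (225.0, 0), (10.0, 1), (90.0, 1), (9.99, 0), (90.01, 0), (0.0, 0),
    ])
    def test_north_east_sector_closed_endpoints(self, deg, expected):
        assert assign_treatment(deg) == expected

    def test_wrapping_sector(self):
        assert assign_treatment(355.0, sector=(350, 30)) == 1
        assert assign_treatment(20.0, sector=(350, 30)) == 1
        assert assign_treatment(180.0, sector=(350, 30)) == 0

    @pytest.mark.parametrize("bad", [400.0, -5.0, 360.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_treatment(bad)

    def test_vectorized_and_nan_propagation(self):
        out = assign_treatment(np.array([45.0, 225.0]))
        assert out.tolist() == [1, 0]
        out = assign_treatment(np.array([45.0, np.nan]))
        assert out[0] == 1.0 and np.isnan(out[1])


class TestReadDailyDataset:
    @staticmethod
    def _csv(tmp_path, rows, **cols):
        df = pd.DataFrame({
            "date": pd.date_range("2015-03-06", periods=rows).strftime("%Y-%m-%d"),
            "temperature": np.linspace(5, 7, rows),
            "wind_speed": 3.0, "wind_direction": 45.0, "humidity": 70.0,
            "pm10": 20.0,
        } | cols)
        path = tmp_path / "daily.csv"
        df.to_csv(path, index=False)
        return path

    def test_three_row_construction(self, tmp_path):
        df = read_daily_dataset(self._csv(tmp_path, 3))
        assert len(df) == 3
        assert df["julian"].tolist() == [0, 1, 2]
        assert df["w"].tolist() == [1, 1, 1]          # 45 deg is in the NE sector
        assert df["weekend"].tolist() == [0, 1, 1]    # 2015-03-06 was a Friday
        assert df["month"].tolist() == [3, 3, 3]

    def test_duplicate_dates_rejected(self, tmp_path):
        path = self._csv(tmp_path, 3)
        raw = pd.read_csv(path)
        raw.loc[2, "date"] = raw.loc[1, "date"]
        raw.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicate"):
            read_daily_dataset(path)

    def test_out_of_range_wind_direction_names_row(self, tmp_path):
        path = self._csv(tmp_path, 3, wind_direction=[45.0, 400.0, 45.0])
        with pytest.raises(ValueError, match="row 1"):
            read_daily_dataset(path)

    def test_out_of_range_humidity_rejected(self, tmp_path):
        path = self._csv(tmp_path, 3, humidity=[70.0, 150.0, 70.0])
        with pytest.raises(ValueError, match="humidity"):
            read_daily_dataset(path)

    def test_round_trip_preserves_values(self, tmp_path):
        sds = generate_dataset(SyntheticConfig(n_days=60), seed=5)
        sds = inject_missingness(sds, {"pm10": 0.1}, seed=5)
        path = tmp_path / "rt.csv"
        write_daily_dataset(sds.observed, path)
        back = read_daily_dataset(path)
        for col in ("pm10", "no2", "temperature", "wind_direction", "w"):
            a = sds.observed[col].to_numpy(dtype=float)
            b = back[col].to_numpy(dtype=float)
            both = ~np.isnan(a)
            assert np.array_equal(np.isnan(a), np.isnan(b))
            assert np.array_equal(a[both], b[both])


class TestLagsAndLeads:
    def test_lag_name_round_trip(self):
        for var, off in [("pm10", -1), ("w", -1), ("o3", 2), ("no2", 1)]:
            assert parse_lag_name(lag_name(var, off)) == (var, off)

    def test_constant_series_lag(self):
        df = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=5), "x": 7.0})
        out = add_lags_and_leads(df, ["x"], [-1])
        assert np.isnan(out["x_lag1"].iloc[0])
        assert (out["x_lag1"].iloc[1:] == 7.0).all()

    def test_lead_shifts_forward(self):
        df = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=3),
                           "x": [1.0, 2.0, 3.0]})
        out = add_lags_and_leads(df, ["x"], [1])
        assert out["x_lead1"].tolist()[:2] == [2.0, 3.0]
        assert np.isnan(out["x_lead1"].iloc[2])

    def test_lag_across_date_gap_is_missing(self):
        dates = pd.to_datetime(["2015-01-01", "2015-01-02", "2015-01-05",
                                "2015-01-06", "2015-01-07"])
        df = pd.DataFrame({"date": dates, "x": [1.0, 2.0, 3.0, 4.0, 5.0]})
        out = add_lags_and_leads(df, ["x"], [-1])
        # Jan 5 has no Jan 4 row: lag must be missing, not 2.0
        assert np.isnan(out.loc[2, "x_lag1"])
        assert out.loc[3, "x_lag1"] == 3.0

    def test_lead_is_inverse_of_lag(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=50),
                           "x": rng.normal(size=50)})
        out = add_lags_and_leads(df, ["x"], [-1, 1])
        lead = out["x_lead1"].to_numpy()[:-1]
        lag = out["x_lag1"].to_numpy()[1:]
        assert np.allclose(lead, out["x"].to_numpy()[1:])
        assert np.allclose(lag, out["x"].to_numpy()[:-1])

    def test_unknown_variable_rejected(self):
        df = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=3), "x": 1.0})
        with pytest.raises(ValueError, match="unknown"):
            add_lags_and_leads(df, ["y"], [-1])


class TestImputation:
    def test_complete_data_unchanged(self):
        df = generate_dataset(SyntheticConfig(n_days=120), seed=2).observed
        out = impute_missing(df, seed=2)
        flags = out.filter(like="imputed_")
        assert not flags.to_numpy().any()
        pd.testing.assert_frame_equal(out[df.columns], df)

    def test_linear_relation_recovered_by_linear_learner(self):
        n = 40
        temp = np.linspace(0.0, 20.0, n)
        df = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=n),
                           "temperature": temp, "pm10": 2.0 * temp})
        df.loc[17, "pm10"] = np.nan
        out = impute_missing(df, exclude=(), learner="linear", seed=0)
        assert out.loc[17, "pm10"] == pytest.approx(2.0 * temp[17], abs=0.05)
        assert bool(out.loc[17, "imputed_pm10"])

    def test_excluded_variable_left_missing(self):
        sds = generate_dataset(SyntheticConfig(n_days=300), seed=3)
        sds = inject_missingness(sds, {"pm25": 0.25, "pm10": 0.05}, seed=3)
        out = impute_missing(sds.observed, exclude=("pm25",), learner="linear", seed=3)
        assert out["pm25"].isna().sum() == sds.observed["pm25"].isna().sum()
        assert out["pm10"].isna().sum() == 0
        assert out["imputed_pm10"].sum() == sds.observed["pm10"].isna().sum()

    def test_variable_with_no_observations_rejected(self):
        df = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=5),
                           "temperature": 1.0, "pm10": np.nan})
        with pytest.raises(ValueError, match="zero observed"):
            impute_missing(df, exclude=(), learner="linear")


class TestEvaluateImputation:
    def test_constant_column_has_zero_error(self):
        n = 60
        df = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=n),
                           "temperature": np.linspace(0, 10, n), "pm10": 15.0})
        table = evaluate_imputation(df, 0.2, learner="linear", seed=1,
                                    variables=["pm10"], exclude=())
        assert table.loc[0, "mae"] == pytest.approx(0.0, abs=1e-6)
        assert table.loc[0, "observed_mean"] == pytest.approx(15.0)

    def test_reproducible_per_seed_and_seed_sensitive(self):
        df = generate_dataset(SyntheticConfig(n_days=200), seed=6).observed
        a = evaluate_imputation(df, 0.1, learner="linear", seed=10)
        b = evaluate_imputation(df, 0.1, learner="linear", seed=10)
        c = evaluate_imputation(df, 0.1, learner="linear", seed=11)
        pd.testing.assert_frame_equal(a, b)
        assert not a["mae"].equals(c["mae"])

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_bad_mask_fraction_rejected(self, frac):
        df = pd.DataFrame({"date": pd.date_range("2015-01-01", periods=5),
                           "pm10": 1.0})
        with pytest.raises(ValueError):
            evaluate_imputation(df, frac)
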