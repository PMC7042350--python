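"""Depth integration, MLD, time encodings, monthly aggregation, gap filling."""

import datetime as dt
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gyretrend.dataset import (
    CastRecord, MonthlySeries,
    build_feature_table, complete_cases, density_gradient,
    fill_gaps_month_means, integrate_profile, mean_temperature,
    mixed_layer_depth, monthly_aggregate, read_casts_csv, read_feature_csv,
    time_features, write_casts_csv, write_feature_csv,
)


class TestIntegrateProfile:
    def test_constant_profile(self):
        assert integrate_profile(([0, 60, 120], [2, 2, 2])) == pytest.approx(240.0)

    def test_linear_ramp_exact(self):
        # trapezoid is exact for v(z) = z: 120^2 / 2
        assert integrate_profile(([0, 60, 120], [0, 60, 120])) == pytest.approx(7200.0)

    def test_nearest_extension_below_deepest_sample(self):
        # hand trapezoid: 100 + 200 + constant-extension 5*20 = 400
        assert integrate_profile(([0, 50, 100], [1, 3, 5])) == pytest.approx(400.0)

    def test_boundary_interpolation(self):
        # samples bracketing both boundaries: interpolate at 0 and 120
        val = integrate_profile(([-0.0, 40, 160], [0.0, 40.0, 160.0]))
        assert val == pytest.approx(7200.0)

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError):
            integrate_profile(([], []))

    def test_single_sample_constant_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert integrate_profile(([30], [4.0])) == pytest.approx(480.0)
        assert any("single-sample" in r.message for r in caplog.records)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=8),
           st.floats(0.1, 5.0), st.floats(-10, 10))
    def test_linearity_in_values(self, vals, a, b):
        z = np.linspace(0, 120, len(vals))
        v = np.asarray(vals)
        lhs = integrate_profile((z, a * v + b))
        rhs = a * integrate_profile((z, v)) + b * 120.0
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=8),
           st.floats(10, 110))
    def test_additive_over_subintervals(self, vals, z_mid):
        z = np.linspace(0, 120, len(vals))
        v = np.asarray(vals)
        total = integrate_profile((z, v), 0, 120)
        split = (integrate_profile((z, v), 0, z_mid)
                 + integrate_profile((z, v), z_mid, 120))
        assert total == pytest.approx(split, rel=1e-9, abs=1e-6)


class TestMeanTemperature:
    def test_constant(self):
        assert mean_temperature(([0, 30, 120], [18, 18, 18])) == pytest.approx(18.0)

    def test_linear_ramp(self):
        assert mean_temperature(([0, 60, 120], [0, 60, 120])) == pytest.approx(60.0)

    def test_two_point_profile(self):
        assert mean_temperature(([0, 120], [20, 10])) == pytest.approx(15.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-5, 35), st.integers(2, 10))
    def test_constant_profile_any_grid(self, value, n):
        z = np.linspace(0, 120, n)
        assert mean_temperature((z, np.full(n, value))) == pytest.approx(value)


class TestDensityGradient:
    def test_homogeneous_column(self):
        prof = ([0, 20, 120], [1025.0, 1025.0, 1025.0])
        assert density_gradient(prof) == pytest.approx(1.0)

    def test_direct_ratio(self):
        prof = ([0, 20, 120], [1024.0, 1024.0, 1026.0])
        assert density_gradient(prof) == pytest.approx(1024.0 / 1026.0)

    def test_interpolated_anchor(self):
        # rho(20) = 1024.5 by interpolation between (10, 1024) and (30, 1025)
        prof = ([10, 30, 120], [1024.0, 1025.0, 1026.0])
        assert density_gradient(prof) == pytest.approx(1024.5 / 1026.0)

    def test_orientation_flag(self):
        prof = ([0, 20, 120], [1024.0, 1024.0, 1026.0])
        assert density_gradient(prof, orientation="deep_over_shallow") == \
            pytest.approx(1026.0 / 1024.0)

    def test_missing_anchor_errors(self):
        with pytest.raises(ValueError):
            density_gradient(([0, 20, 100], [1024, 1024, 1025]))  # no 120 m


class TestMixedLayerDepth:
    def test_step_profile_interpolated_crossing(self):
        # uniform to 60 m, +0.5 step at 80 m: crossing at 60 + (0.125/0.5)*20
        prof = ([0, 20, 40, 60, 80], [1025.0] * 4 + [1025.5])
        assert mixed_layer_depth(prof) == pytest.approx(65.0)

    def test_homogeneous_profile_returns_deepest(self):
        prof = ([0, 40, 80, 120], [1025.0] * 4)
        assert mixed_layer_depth(prof) == pytest.approx(120.0)

    def test_zero_threshold_degenerate(self):
        prof = ([5, 40, 80], [1025.0, 1025.3, 1026.0])
        assert mixed_layer_depth(prof, threshold=0.0) == pytest.approx(5.0)

    def test_one_point_profile_errors(self):
        with pytest.raises(ValueError):
            mixed_layer_depth(([0], [1025.0]))

    def test_deep_first_sample_errors(self):
        with pytest.raises(ValueError):
            mixed_layer_depth(([20, 60], [1025.0, 1026.0]))


class TestTimeFeatures:
    def test_origin_day(self):
        assert time_features(dt.date(1990, 1, 1), dt.date(1990, 1, 1)) == (0, 1)

    def test_end_of_common_year(self):
        _, x2 = time_features(dt.date(1990, 12, 31), dt.date(1990, 1, 1))
        assert x2 == 365

    def test_leap_day(self):
        x1, x2 = time_features(dt.date(1992, 2, 29), dt.date(1990, 1, 1))
        assert (x1, x2) == (789, 60)

    def test_date_before_origin_errors(self):
        with pytest.raises(ValueError):
            time_features(dt.date(1989, 12, 31), dt.date(1990, 1, 1))

    def test_periodic_pair_unit_circle(self):
        *_, (s, c) = time_features(dt.date(1990, 7, 1), dt.date(1990, 1, 1),
                                   periodic=True)
        assert s * s + c * c == pytest.approx(1.0)


class TestMonthlyAggregate:
    def test_mean_of_two_casts(self):
        series = monthly_aggregate([(dt.date(1990, 1, 5), 4.0),
                                    (dt.date(1990, 1, 20), 6.0),
                                    (dt.date(1990, 7, 15), 3.0)])
        years, vals = series.month_values(1)
        assert vals[0] == pytest.approx(5.0)

    def test_empty_month_missing(self):
        series = monthly_aggregate([(dt.date(1990, 1, 5), 4.0),
                                    (dt.date(1990, 3, 5), 2.0)])
        _, feb = series.month_values(2)
        assert np.isnan(feb[0])

    def test_fortnightly_and_monthly_both_one_value(self):
        series = monthly_aggregate([(dt.date(1990, 1, 7), 1.0),
                                    (dt.date(1990, 1, 21), 3.0),
                                    (dt.date(1990, 7, 15), 9.0)])
        assert series.month_values(1)[1][0] == pytest.approx(2.0)
        assert series.month_values(7)[1][0] == pytest.approx(9.0)

    def test_median_statistic(self):
        series = monthly_aggregate([(dt.date(1990, 1, 1), 1.0),
                                    (dt.date(1990, 1, 10), 2.0),
                                    (dt.date(1990, 1, 20), 9.0)],
                                   statistic="median")
        assert series.month_values(1)[1][0] == pytest.approx(2.0)


class TestFillGaps:
    def test_fill_with_month_mean(self):
        s = MonthlySeries.from_pairs([(1990, 1, 10.0), (1991, 1, None),
                                      (1992, 1, 14.0)])
        filled = fill_gaps_month_means(s)
        jan = filled.month_values(1)[1]
        assert jan[1] == pytest.approx(12.0)

    def test_identity_when_no_gaps(self):
        s = MonthlySeries(np.array([1990, 1990]), np.array([1, 2]),
                          np.array([1.0, 2.0]))
        filled = fill_gaps_month_means(s)
        np.testing.assert_array_equal(filled.values, s.values)

    def test_month_absent_everywhere_stays_missing(self, caplog):
        s = MonthlySeries.from_pairs([(1990, 1, 10.0), (1991, 1, 12.0)])
        with caplog.at_level(logging.WARNING):
            filled = fill_gaps_month_means(s)
        assert np.isnan(filled.month_values(6)[1]).all()
        assert any("remain missing" in r.message for r in caplog.records)

    def test_idempotent(self):
        s = MonthlySeries.from_pairs([(1990, m, float(m)) for m in range(1, 10)]
                                     + [(1991, m, float(m) + 1) for m in range(3, 13)])
        once = fill_gaps_month_means(s)
        twice = fill_gaps_month_means(once)
        np.testing.assert_array_equal(once.values, twice.values)


class TestCompleteCases:
    def test_no_missing_identity(self, feature_frame):
        kept, log_df = complete_cases(feature_frame)
        assert len(kept) == len(feature_frame) and log_df.empty

    def test_single_missing_field_drops_only_that_row(self, feature_frame):
        df = feature_frame.copy()
        df.loc[3, "po4"] = np.nan
        kept, log_df = complete_cases(df)
        assert len(kept) == len(df) - 1
        assert log_df.iloc[0]["missing_columns"] == "po4"
        pd.testing.assert_frame_equal(kept, df.drop(index=3))

    def test_all_rows_missing_warns_and_empties(self, feature_frame, caplog):
        df = feature_frame.copy()
        df["no3"] = np.nan
        with caplog.at_level(logging.WARNING):
            kept, _ = complete_cases(df)
        assert kept.empty


class TestMonthlySeriesContract:
    def test_duplicate_month_rejected(self):
        with pytest.raises(ValueError):
            MonthlySeries(np.array([1990, 1990]), np.array([1, 1]),
                          np.array([1.0, 2.0]))

    def test_month_range_enforced(self):
        with pytest.raises(ValueError):
            MonthlySeries(np.array([1990]), np.array([13]), np.array([1.0]))


class TestCastRecordAndIO:
    def _cast(self, day=15):
        z = np.arange(0, 121, 20, dtype=float)
        return CastRecord(dt.date(1990, 1, day), {
            "temp": (z, 20.0 - z / 20.0),
            "dens": (z, 1025.0 + z / 100.0),
            "no3": (z, z / 60.0),
        }, npp=400.0)

    def test_decreasing_depths_rejected(self):
        with pytest.raises(ValueError):
            CastRecord(dt.date(1990, 1, 1),
                       {"temp": ([10, 5], [20.0, 19.0])})

    def test_roundtrip_csv(self, tmp_path):
        casts = [self._cast(5), self._cast(25)]
        write_casts_csv(casts, tmp_path / "c.csv", tmp_path / "n.csv")
        header = (tmp_path / "c.csv").read_text().splitlines()[0]
        assert header == "date,depth,temp,dens,no3,po4,sio2,chla,chlb,fuco,lutzea"
        back = read_casts_csv(tmp_path / "c.csv", tmp_path / "n.csv")
        assert len(back) == 2
        np.testing.assert_allclose(back[0].profiles["temp"][1],
                                   casts[0].profiles["temp"][1])
        assert back[0].npp == pytest.approx(400.0)

    def test_feature_table_and_csv(self, tmp_path):
        table = build_feature_table([self._cast(5), self._cast(25)])
        assert list(table.columns)[0] == "date"
        assert table["temp"].iloc[0] == pytest.approx(
            mean_temperature((np.arange(0, 121, 20), 20.0 - np.arange(0, 121, 20) / 20.0)))
        write_feature_csv(table, tmp_path / "f.csv")
        back = read_feature_csv(tmp_path / "f.csv")
        np.testing.assert_allclose(back["npp"], table["npp"])
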