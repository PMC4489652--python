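"""Catalog reading, validation, daily binning and descriptive tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import selfexcite as sx
from selfexcite.event_io import RowError, SchemaError

from conftest import make_catalog_df, write_csv


class TestReadCatalog:
    def test_reads_sorted_and_validated(self, small_catalog):
        assert len(small_catalog) == 5
        assert small_catalog.dates.is_monotonic_increasing
        assert small_catalog.date_span == (
            pd.Timestamp("2010-01-01").date(),
            pd.Timestamp("2010-01-09").date(),
        )

    def test_firearm_filter_and_report(self, tmp_path, small_catalog):
        df = small_catalog.data.copy()
        path = write_csv(tmp_path, df)
        cat = sx.read_catalog(path, filters={"firearm": True})
        assert len(cat) == 4
        assert cat.data["firearm"].all()
        steps = [s[0] for s in cat.filter_report]
        assert steps == ["read", "firearm=True"]
        assert cat.filter_report[-1][1:] == (5, 4)

    def test_min_max_killed_filters(self, small_catalog):
        kept = sx.apply_filters(small_catalog, {"min_killed": 5})
        assert kept.data["n_killed"].min() >= 5
        kept = sx.apply_filters(small_catalog, {"max_killed": 4})
        assert kept.data["n_killed"].max() <= 4

    def test_filter_idempotent(self, small_catalog):
        once = sx.apply_filters(small_catalog, {"firearm": True})
        twice = sx.apply_filters(once, {"firearm": True})
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_empty_file_valid_header(self, tmp_path):
        path = write_csv(tmp_path, make_catalog_df([]))
        cat = sx.read_catalog(path)
        assert len(cat) == 0
        assert cat.date_span is None

    def test_bad_date_names_offending_row(self, tmp_path):
        df = make_catalog_df(
            [
                ("2010-01-01", "TX", 31.5, -99.3, 4, True, False),
                ("2010-01-02", "CA", 37.2, -119.3, 5, True, True),
                ("not-a-date", "NY", 42.9, -75.5, 4, False, False),
                ("2010-01-05", "FL", 28.6, -82.4, 6, True, True),
                ("2010-01-09", "OH", 40.3, -82.8, 4, True, False),
            ]
        )
        with pytest.raises(RowError) as err:
            sx.read_catalog(write_csv(tmp_path, df))
        assert err.value.rows == [3]
        assert "3" in str(err.value)

    def test_missing_column_named(self, tmp_path):
        df = make_catalog_df([("2010-01-01", "TX", 31.5, -99.3, 4, True, False)])
        df = df.drop(columns=["date"])
        with pytest.raises(SchemaError, match="date"):
            sx.read_catalog(write_csv(tmp_path, df))

    def test_column_map_renames(self, tmp_path):
        df = make_catalog_df([("2010-01-01", "TX", 31.5, -99.3, 4, True, False)])
        df = df.rename(columns={"date": "Incident Date"})
        cat = sx.read_catalog(
            write_csv(tmp_path, df), column_map={"Incident Date": "date"}
        )
        assert len(cat) == 1

    def test_out_of_range_coordinates_rejected(self, tmp_path):
        df = make_catalog_df([("2010-01-01", "TX", 95.0, -99.3, 4, True, False)])
        with pytest.raises(RowError):
            sx.read_catalog(write_csv(tmp_path, df))


class TestDailySeries:
    def test_counts_by_definition(self, small_catalog):
        series = sx.to_daily_series(small_catalog)
        # events on Jan 1 (x2), 2, 5, 9 -> 9-day grid
        assert series.n_days == 9
        assert series.counts.tolist() == [2, 1, 0, 0, 1, 0, 0, 0, 1]
        assert series.n_events == len(small_catalog)

    def test_span_length_is_inclusive(self, synthetic_catalog):
        series = sx.to_daily_series(synthetic_catalog)
        first, last = synthetic_catalog.date_span
        assert series.n_days == (last - first).days + 1
        assert series.n_events == len(synthetic_catalog)

    def test_round_trip_recovers_date_multiset(self, synthetic_catalog):
        from selfexcite.event_io import series_to_dates

        series = sx.to_daily_series(synthetic_catalog)
        back = series_to_dates(series)
        assert sorted(back) == sorted(synthetic_catalog.dates)

    def test_empty_catalog_rejected(self, tmp_path):
        cat = sx.read_catalog(write_csv(tmp_path, make_catalog_df([])))
        with pytest.raises(sx.CatalogError):
            sx.to_daily_series(cat)


class TestCalendarTests:
    def test_exposure_proportional_counts_give_null(self, tmp_path):
        # one event per day over exactly 4 weeks: counts proportional to exposure
        days = pd.date_range("2010-01-04", periods=28, freq="D")
        df = make_catalog_df(
            [(d.strftime("%Y-%m-%d"), "TX", 31.5, -99.3, 4, True, False) for d in days]
        )
        res = sx.weekday_seasonal_tests(sx.read_catalog(write_csv(tmp_path, df)))
        assert res.weekday_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.weekday_p == pytest.approx(1.0)

    def test_all_events_on_sundays_hand_computed(self, tmp_path):
        # 14 events, 7 on each of two consecutive Sundays.  Span is
        # 2010-01-10..2010-01-17 (8 days): exposure 2 Sundays, 1 of each
        # other weekday; expected counts 3.5 and 1.75.  Hand computation:
        # chi2 = (14-3.5)^2/3.5 + 6*(0-1.75)^2/1.75 = 31.5 + 10.5 = 42.
        rows = [("2010-01-10", "TX", 31.5, -99.3, 4, True, False)] * 7
        rows += [("2010-01-17", "TX", 31.5, -99.3, 4, True, False)] * 7
        df = make_catalog_df(rows)
        res = sx.weekday_seasonal_tests(sx.read_catalog(write_csv(tmp_path, df)))
        assert res.weekday_df == 6
        assert res.n_events == 14
        assert res.weekday_chi2 == pytest.approx(42.0)

    def test_uniform_expected_chi2_hand_computed(self):
        # with 2 expected per weekday and all 14 observations in one cell,
        # Pearson chi2 = 6*(0-2)^2/2 + (14-2)^2/2 = 12 + 72 = 84
        obs = np.array([0, 0, 0, 0, 0, 0, 14.0])
        exp = np.full(7, 2.0)
        chi2, _ = stats.chisquare(obs, exp)
        assert chi2 == pytest.approx(84.0)

    def test_school_year_imbalance_detected(self, tmp_path):
        # all events Sep-Apr over a 2-year span
        days = pd.date_range("2010-09-01", "2011-04-30", freq="7D")
        rows = [(d.strftime("%Y-%m-%d"), "TX", 31.5, -99.3, 4, True, False) for d in days]
        rows.append(("2012-08-31", "TX", 31.5, -99.3, 4, True, False))
        df = make_catalog_df(rows)
        res = sx.weekday_seasonal_tests(sx.read_catalog(write_csv(tmp_path, df)))
        assert res.school_year_events == len(days)
        assert res.school_year_p < 0.05

    def test_short_span_rejected(self, tmp_path):
        df = make_catalog_df(
            [
                ("2010-01-01", "TX", 31.5, -99.3, 4, True, False),
                ("2010-01-03", "CA", 37.2, -119.3, 4, True, False),
            ]
        )
        with pytest.raises(sx.CatalogError):
            sx.weekday_seasonal_tests(sx.read_catalog(write_csv(tmp_path, df)))

    def test_weekday_p_uniform_under_null(self):
        """Exposure-proportional multinomial counts give uniform p-values."""
        rng = np.random.default_rng(123)
        n_events, reps = 700, 2000
        obs = rng.multinomial(n_events, np.ones(7) / 7.0, size=reps)
        expected = np.full(7, n_events / 7.0)
        _, pvals = stats.chisquare(obs, expected, axis=1)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestSeverityComparison:
    def test_identical_subgroups_symmetric(self, tmp_path):
        rows = [
            ("2010-01-01", "TX", 31.5, -99.3, 4, True, True),
            ("2010-01-02", "TX", 31.5, -99.3, 5, True, True),
            ("2010-01-03", "TX", 31.5, -99.3, 4, True, False),
            ("2010-01-04", "TX", 31.5, -99.3, 5, True, False),
        ]
        res = sx.suicide_severity_comparison(
            sx.read_catalog(write_csv(tmp_path, make_catalog_df(rows)))
        )
        assert res.ratio == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)
        assert res.suicide_fraction == pytest.approx(0.5)

    def test_degenerate_separated_groups(self, tmp_path):
        rows = [("2010-01-0%d" % (i + 1), "TX", 31.5, -99.3, 5, True, True) for i in range(4)]
        rows += [("2010-01-0%d" % (i + 5), "TX", 31.5, -99.3, 4, True, False) for i in range(4)]
        res = sx.suicide_severity_comparison(
            sx.read_catalog(write_csv(tmp_path, make_catalog_df(rows)))
        )
        assert res.ratio == pytest.approx(1.25)
        assert res.p_value < 1e-6

    def test_empty_subgroup_marked_unavailable(self, tmp_path):
        rows = [("2010-01-01", "TX", 31.5, -99.3, 4, True, True)] * 3
        res = sx.suicide_severity_comparison(
            sx.read_catalog(write_csv(tmp_path, make_catalog_df(rows)))
        )
        assert not res.available
        assert res.p_value is None
        assert res.suicide_fraction == pytest.approx(1.0)

    def test_severity_gap_recovered_on_synthetic(self, tmp_path):
        rng = np.random.default_rng(5)
        rows = []
        for i in range(200):
            suicide = i % 2 == 0
            killed = 4 + rng.poisson(5.0 if suicide else 1.0)
            rows.append(
                (
                    (pd.Timestamp("2010-01-01") + pd.Timedelta(days=i)).strftime("%Y-%m-%d"),
                    "TX", 31.5, -99.3, killed, True, suicide,
                )
            )
        res = sx.suicide_severity_comparison(
            sx.read_catalog(write_csv(tmp_path, make_catalog_df(rows)))
        )
        assert res.ratio > 1.5
        assert res.p_value < 0.001
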