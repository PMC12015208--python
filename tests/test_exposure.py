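"""Heat-wave exposure metrics: aggregation, thresholds, window statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from heatbirth.exposure import (
    MissingExposureError,
    ZctaTempSeries,
    exposure_for_date,
    exposure_table,
    hot_day_threshold,
    window_aat,
    window_metrics,
    window_run_length,
    zcta_daily_series,
)


def _grid(points, dates, tmin, tmax):
    rows = []
    for p, lo, hi in zip(points, tmin, tmax):
        for d in dates:
            rows.append({"point_id": p, "date": d, "tmin_c": lo, "tmax_c": hi})
    return pd.DataFrame(rows)


class TestZctaAggregation:
    dates = pd.date_range("2010-06-01", periods=3)

    def test_single_point_midpoint(self):
        gt = _grid(["p1"], self.dates, [10.0], [20.0])
        gm = pd.DataFrame({"point_id": ["p1"], "zcta_id": ["Z1"]})
        series = zcta_daily_series(gt, gm)
        assert np.allclose(series["Z1"].tmean, 15.0)

    def test_two_point_average(self):
        gt = _grid(["p1", "p2"], self.dates, [10.0, 20.0], [20.0, 30.0])
        gm = pd.DataFrame({"point_id": ["p1", "p2"], "zcta_id": ["Z1", "Z1"]})
        series = zcta_daily_series(gt, gm)
        # avg_tmin 15, avg_tmax 25 -> midpoint 20
        assert np.allclose(series["Z1"].tmean, 20.0)

    def test_unknown_point_in_map_is_error(self):
        gt = _grid(["p1"], self.dates, [10.0], [20.0])
        gm = pd.DataFrame({"point_id": ["p1", "ghost"], "zcta_id": ["Z1", "Z2"]})
        with pytest.raises(KeyError, match="ghost"):
            zcta_daily_series(gt, gm)

    def test_unmapped_zcta_is_error_naming_it(self):
        gt = _grid(["p1"], self.dates, [10.0], [20.0])
        gm = pd.DataFrame({"point_id": ["p1"], "zcta_id": ["Z1"]})
        with pytest.raises(ValueError, match="Z9"):
            zcta_daily_series(gt, gm, require_zctas=["Z1", "Z9"])

    def test_missing_point_day_is_error(self):
        gt = _grid(["p1", "p2"], self.dates, [10.0, 12.0], [20.0, 22.0])
        gt = gt.drop(gt.index[-1])  # p2 misses one date
        gm = pd.DataFrame({"point_id": ["p1", "p2"], "zcta_id": ["Z1", "Z1"]})
        with pytest.raises(ValueError, match="p2"):
            zcta_daily_series(gt, gm)

    def test_tmin_above_tmax_is_error(self):
        gt = _grid(["p1"], self.dates, [25.0], [20.0])
        gm = pd.DataFrame({"point_id": ["p1"], "zcta_id": ["Z1"]})
        with pytest.raises(ValueError, match="tmin"):
            zcta_daily_series(gt, gm)


class TestThreshold:
    def test_constant_series(self):
        assert hot_day_threshold(np.full(100, 20.0)) == 20.0

    def test_linear_interpolation_convention(self):
        # 1..1000 at the 97.5th percentile under Weibull plotting positions
        assert hot_day_threshold(np.arange(1.0, 1001.0)) == pytest.approx(975.975)

    def test_empty_series_errors(self):
        with pytest.raises(ValueError):
            hot_day_threshold(np.array([]))

    def test_bad_percentile_errors(self):
        with pytest.raises(ValueError):
            hot_day_threshold(np.arange(10.0), percentile=100.0)

    def test_stored_on_series_and_within_range(self, rng):
        t = rng.normal(20, 5, size=400)
        s = ZctaTempSeries("Z", pd.date_range("2000-01-01", periods=400), t)
        thr = hot_day_threshold(s)
        assert s.threshold == thr
        assert t.min() <= thr <= t.max()

    def test_percentile_rank_property(self, rng):
        # distinct values: the share of days at or below the threshold is
        # within 1/n of 0.975
        for n in (200, 1000, 5000):
            t = rng.permutation(n).astype(float)
            thr = hot_day_threshold(t)
            assert abs((t <= thr).mean() - 0.975) <= 1.0 / n


class TestWindowMetrics:
    @pytest.mark.parametrize("pattern", list(itertools.product([0, 1], repeat=4)))
    def test_run_length_matches_brute_force(self, pattern):
        temps = [25.0 if h else 15.0 for h in pattern]
        best = run = 0
        for h in pattern:
            run = run + 1 if h else 0
            best = max(best, run)
        assert window_run_length(temps, 20.0) == best

    def test_tie_at_threshold_is_not_hot(self):
        assert window_run_length([20.0, 20.0, 20.0, 20.0], 20.0) == 0

    def test_wrong_window_size_errors(self):
        with pytest.raises(ValueError):
            window_run_length([21.0, 21.0, 21.0], 20.0)
        with pytest.raises(ValueError):
            window_aat([21.0] * 5, 20.0)

    def test_aat_examples(self):
        assert window_aat([15, 16, 17, 18], 20.0) == 0.0  # negative -> floored
        assert window_aat([21, 21, 21, 21], 20.0) == pytest.approx(1.0)
        # cool days count negatively before the floor
        assert window_aat([22, 22, 19, 19], 20.0) == pytest.approx(0.5)

    @given(
        temps=st.lists(st.floats(-10, 40), min_size=4, max_size=4),
        day=st.integers(0, 3),
        bump=st.floats(0.01, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_any_single_day(self, temps, day, bump):
        thr = 20.0
        hotter = list(temps)
        hotter[day] += bump
        assert window_run_length(hotter, thr) >= window_run_length(temps, thr)
        assert window_aat(hotter, thr) >= window_aat(temps, thr)


class TestExposureForDate:
    def _series(self, temps, start="2010-07-01"):
        s = ZctaTempSeries(
            "Z", pd.date_range(start, periods=len(temps)), np.asarray(temps, float)
        )
        s.threshold = 20.0
        return s

    def test_cool_window_all_zero(self):
        s = self._series([15, 15, 15, 15, 15])
        e = exposure_for_date(s, "2010-07-05")
        assert e.run_length == 0 and e.aat == 0.0
        assert not (e.hw_ge2 or e.hw_ge3 or e.hw_eq4)

    def test_hottest_window_flags_eq4_and_exact_aat(self):
        temps = [15.0] * 6 + [25.0, 26.0, 27.0, 28.0]
        s = self._series(temps)
        e = exposure_for_date(s, "2010-07-10")
        assert e.hw_eq4 and e.hw_ge3 and e.hw_ge2
        # no floor engaged: aat equals window mean minus threshold exactly
        assert e.aat == pytest.approx(np.mean(temps[-4:]) - 20.0, abs=1e-12)

    def test_window_before_series_start_signals_missing(self):
        s = self._series([15, 15, 15, 15], start="2010-01-01")
        with pytest.raises(MissingExposureError):
            exposure_for_date(s, "2010-01-02")

    def test_table_matches_per_date_function(self, rng):
        t = rng.normal(20, 5, size=60)
        s = ZctaTempSeries("Z", pd.date_range("2010-06-01", periods=60), t)
        hot_day_threshold(s)
        tab = exposure_table({"Z": s}).set_index("date")
        for date in s.dates[3:]:
            e = exposure_for_date(s, date)
            row = tab.loc[date]
            assert row["run_length"] == e.run_length
            assert row["aat"] == pytest.approx(e.aat, abs=1e-12)
            assert bool(row["hw_eq4"]) == e.hw_eq4

    def test_indicator_nesting(self, rng):
        t = rng.normal(22, 4, size=300)
        s = ZctaTempSeries("Z", pd.date_range("2010-01-01", periods=300), t)
        tab = exposure_table({"Z": s})
        assert (tab["hw_eq4"] <= tab["hw_ge3"]).all()
        assert (tab["hw_ge3"] <= tab["hw_ge2"]).all()

    def test_window_metrics_agrees_with_scalar_ops(self, rng):
        t = rng.normal(20, 6, size=100)
        thr = hot_day_threshold(t)
        first, rl, aat = window_metrics(t, thr)
        for k, i in enumerate(range(first, len(t))):
            w = t[i - 3 : i + 1]
            assert rl[k] == window_run_length(w, thr)
            assert aat[k] == pytest.approx(window_aat(w, thr), abs=1e-12)
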