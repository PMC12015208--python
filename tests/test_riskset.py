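"""Pregnancy risk-set adjustment W_i: hazards, counts, oracle agreement."""

import numpy as np
import pandas as pd
import pytest

from heatbirth.design import OUTCOME_WEEKS
from heatbirth.riskset import (
    adjustment_series,
    adjustment_table,
    birth_week_hazard,
    gestational_week_on_day,
)


class TestWeekOnDay:
    def test_day_before_birth(self):
        # ga 36: 7*36 - 1 = 251 days elapsed -> week 35
        assert gestational_week_on_day("2010-10-01", 36, "2010-09-30") == 35

    def test_first_day_is_week_zero(self):
        start = pd.Timestamp("2010-10-01") - pd.Timedelta(days=7 * 36)
        assert gestational_week_on_day("2010-10-01", 36, start) == 0

    def test_birth_day_not_ongoing(self):
        assert gestational_week_on_day("2010-10-01", 36, "2010-10-01") is None

    def test_before_conception_not_ongoing(self):
        early = pd.Timestamp("2010-10-01") - pd.Timedelta(days=7 * 36 + 1)
        assert gestational_week_on_day("2010-10-01", 36, early) is None


class TestWeekHazard:
    def test_hand_counted_hazard(self):
        births = pd.DataFrame({"ga_weeks": [39, 39, 40, 40]})
        wh = birth_week_hazard(births).set_index("ga_weeks")["w_g"]
        assert wh.loc[39] == 0.5 and wh.loc[40] == 1.0

    def test_degenerate_all_one_week(self):
        births = pd.DataFrame({"ga_weeks": [39] * 8})
        wh = birth_week_hazard(births).set_index("ga_weeks")["w_g"]
        assert wh.loc[39] == 1.0

    def test_marginal_method(self):
        births = pd.DataFrame({"ga_weeks": [39, 39, 40, 40]})
        wh = birth_week_hazard(births, method="marginal").set_index("ga_weeks")
        assert np.allclose(wh["w_g"], [0.5, 0.5])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            birth_week_hazard(pd.DataFrame({"ga_weeks": []}))


def _hazard_for(weeks_values: dict) -> pd.DataFrame:
    weeks = sorted(weeks_values)
    return pd.DataFrame(
        {"ga_weeks": weeks, "w_g": [weeks_values[g] for g in weeks],
         "n_births": 1, "n_at_risk": 1}
    )


class TestAdjustmentSeries:
    def _births(self, ga_list, birth_date="2010-09-01"):
        return pd.DataFrame(
            {
                "zcta_id": "Z1",
                "birth_date": pd.Timestamp(birth_date),
                "ga_weeks": ga_list,
            }
        )

    def test_hand_arithmetic_example(self):
        # day i: 2 fetuses at week 28 (W=0.01), 3 at week 30 (W=0.02),
        # 5 more ongoing outside the risk range -> W_i = 0.008
        day = pd.Timestamp("2010-06-01")
        rows = []
        for g, n in [(28, 2), (30, 3), (20, 3), (40, 2)]:
            for _ in range(n):
                # choose birth so the pregnancy is at week g on `day`
                rows.append(
                    {"zcta_id": "Z1",
                     "birth_date": day + pd.Timedelta(days=7 * (45 - g)),
                     "ga_weeks": 45}
                )
        births = pd.DataFrame(rows)
        wh = _hazard_for({g: {28: 0.01, 30: 0.02}.get(g, 0.5) for g in range(20, 46)})
        out = adjustment_table(births, [day], "PTB", wh)
        row = out.iloc[0]
        assert row["z_total"] == 10
        assert row["w_i"] == pytest.approx((2 * 0.01 + 3 * 0.02) / 10)

    def test_constant_hazard_identity(self):
        # every ongoing fetus inside the risk range, constant W_g = w -> W_i = w
        day = pd.Timestamp("2010-06-01")
        births = pd.DataFrame(
            {"zcta_id": "Z1",
             "birth_date": [day + pd.Timedelta(days=7 * (45 - g)) for g in (28, 30, 35)],
             "ga_weeks": 45}
        )
        wh = _hazard_for({g: 0.03 for g in range(20, 46)})
        out = adjustment_table(births, [day], "PTB", wh)
        assert out["w_i"].iloc[0] == pytest.approx(0.03)

    def test_nobody_in_risk_range_gives_zero(self):
        day = pd.Timestamp("2010-06-01")
        births = pd.DataFrame(
            {"zcta_id": "Z1",
             "birth_date": [day + pd.Timedelta(days=7 * (45 - g)) for g in (20, 40)],
             "ga_weeks": 45}
        )
        wh = _hazard_for({g: 0.03 for g in range(20, 46)})
        out = adjustment_table(births, [day], "PTB", wh)
        assert out["z_total"].iloc[0] == 2 and out["w_i"].iloc[0] == 0.0

    def test_empty_risk_set_is_nan(self):
        births = self._births([40])
        wh = _hazard_for({g: 0.03 for g in range(20, 46)})
        out = adjustment_table(births, ["2012-01-01"], "PTB", wh)
        assert out["z_total"].iloc[0] == 0 and np.isnan(out["w_i"].iloc[0])

    def test_missing_risk_week_in_hazard_errors(self):
        wh = _hazard_for({g: 0.03 for g in range(20, 30)})  # lacks 30..36
        with pytest.raises(ValueError, match="risk-range"):
            adjustment_table(self._births([40]), ["2010-06-01"], "PTB", wh)

    def test_unknown_zcta_errors(self):
        wh = _hazard_for({g: 0.03 for g in range(20, 46)})
        with pytest.raises(ValueError, match="Z9"):
            adjustment_series(self._births([40]), "Z9", ["2010-06-01"], "PTB", wh)


def brute_force_risk_set(births, dates, outcome):
    """Per-pregnancy, per-day enumeration of Z_ig and Z_i."""
    g_lo, g_hi = OUTCOME_WEEKS[outcome]
    zctas = sorted(births["zcta_id"].unique())
    dates = pd.DatetimeIndex(dates)
    z_total = np.zeros((len(zctas), len(dates)), dtype=int)
    zig = np.zeros((len(zctas), len(dates), g_hi - g_lo + 1), dtype=int)
    for _, b in births.iterrows():
        zi = zctas.index(b["zcta_id"])
        for di, day in enumerate(dates):
            g = gestational_week_on_day(b["birth_date"], b["ga_weeks"], day)
            if g is None:
                continue
            z_total[zi, di] += 1
            if g_lo <= g <= g_hi:
                zig[zi, di, g - g_lo] += 1
    return zctas, z_total, zig


@pytest.mark.parametrize("outcome", ["PTB", "ETB"])
def test_vectorized_counts_match_enumeration(rng, outcome):
    n = 50
    births = pd.DataFrame(
        {
            "zcta_id": rng.choice(["Z1", "Z2", "Z3"], size=n),
            "birth_date": pd.Timestamp("2010-06-01")
            + pd.to_timedelta(rng.integers(0, 200, size=n), unit="D"),
            "ga_weeks": rng.integers(25, 44, size=n),
        }
    )
    dates = pd.date_range("2010-05-01", "2010-09-30")
    wh = birth_week_hazard(births)
    out, zig_vec = adjustment_table(births, dates, outcome, wh, return_zig=True)
    zctas, z_total, zig = brute_force_risk_set(births, dates, outcome)
    assert out["zcta_id"].unique().tolist() == zctas
    assert np.array_equal(
        out["z_total"].to_numpy().reshape(len(zctas), -1), z_total
    )
    assert np.array_equal(zig_vec, zig)
    # W_i recomputed from the enumerated counts
    whs = wh.set_index("ga_weeks")["w_g"]
    g_lo, g_hi = OUTCOME_WEEKS[outcome]
    w_ref = zig @ whs.loc[g_lo:g_hi].to_numpy()
    with np.errstate(invalid="ignore"):
        w_ref = np.where(z_total > 0, w_ref / np.maximum(z_total, 1), np.nan)
    w_vec = out["w_i"].to_numpy().reshape(len(zctas), -1)
    assert np.allclose(w_vec, w_ref, atol=1e-12, equal_nan=True)


def test_time_shift_equivariance(rng):
    births = pd.DataFrame(
        {
            "zcta_id": "Z1",
            "birth_date": pd.Timestamp("2010-06-01")
            + pd.to_timedelta(rng.integers(0, 100, size=30), unit="D"),
            "ga_weeks": rng.integers(25, 44, size=30),
        }
    )
    wh = birth_week_hazard(births)
    dates = pd.date_range("2010-04-01", "2010-09-30")
    base = adjustment_table(births, dates, "PTB", wh)
    shifted_births = births.assign(
        birth_date=births["birth_date"] + pd.Timedelta(days=7)
    )
    shifted = adjustment_table(
        shifted_births, dates + pd.Timedelta(days=7), "PTB", wh
    )
    assert np.array_equal(base["z_total"], shifted["z_total"])
    assert np.allclose(base["w_i"], shifted["w_i"], atol=1e-12, equal_nan=True)


def test_w_i_bounded_by_max_hazard(small_sim):
    births = small_sim.births
    wh = birth_week_hazard(births)
    dates = pd.date_range("2001-05-01", "2001-09-30")
    out = adjustment_table(births, dates, "ETB", wh)
    w = out["w_i"].dropna()
    assert (w >= 0).all()
    assert (w <= wh["w_g"].max() + 1e-12).all()


def test_boundary_flag_marks_truncated_tail():
    births = pd.DataFrame(
        {"zcta_id": "Z1",
         "birth_date": pd.to_datetime(["2010-06-01", "2011-06-01"]),
         "ga_weeks": [37, 38]}
    )
    wh = birth_week_hazard(births)
    dates = pd.date_range("2010-05-01", "2011-06-01")
    out = adjustment_table(births, dates, "ETB", wh)
    flagged = out.loc[out["boundary_flag"], "date"]
    assert flagged.min() == pd.Timestamp("2011-06-01") - pd.Timedelta(days=7 * 45 - 1)
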