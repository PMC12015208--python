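"""Heat-wave exposure metrics on ZCTA daily temperature series.

Gridded daily minimum/maximum temperatures are aggregated to ZIP Code
Tabulation Areas (ZCTAs) by unweighted averaging over the grid points
mapped to each ZCTA; the daily mean is the midpoint of the averaged
minimum and maximum.  Hot days are defined relative to a ZCTA-specific
percentile threshold (default the 97.5th percentile of the full-period
daily mean), and two families of heat-wave metrics are computed on a
short trailing window ending on each day:

* ``run_length`` — the longest run of consecutive days in the window
  whose mean temperature strictly exceeds the threshold, dichotomized
  as runs of >=2, >=3 or =4 days (for the default 4-day window);
* ``aat`` — average degrees above threshold: the window-mean
  temperature minus the threshold, floored at zero, in deg C.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ZctaTempSeries",
    "HeatWaveExposure",
    "MissingExposureError",
    "zcta_daily_series",
    "hot_day_threshold",
    "window_run_length",
    "window_aat",
    "window_metrics",
    "exposure_for_date",
    "exposure_table",
]

DEFAULT_PERCENTILE = 97.5
#: Quantile convention: linear interpolation of the empirical CDF at
#: Weibull plotting positions p_k = k/(n+1).  Declared here so an
#: external oracle can reproduce thresholds exactly.
QUANTILE_METHOD = "weibull"
DEFAULT_WINDOW = 4


class MissingExposureError(KeyError):
    """Raised when an exposure window extends outside the temperature series."""


@dataclass
class ZctaTempSeries:
    """Daily mean temperature series for one ZCTA, with hot-day threshold.

    ``dates`` must be a gap-free, strictly increasing daily sequence;
    ``tmean`` the matching daily mean temperatures in deg C.  ``threshold``
    is filled in by :func:`hot_day_threshold` (or at construction).
    """

    zcta_id: str
    dates: pd.DatetimeIndex
    tmean: np.ndarray
    threshold: float | None = None
    _day0: int = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.tmean = np.asarray(self.tmean, dtype=float)
        if len(self.dates) != len(self.tmean):
            raise ValueError("dates and tmean must have equal length")
        if len(self.dates) == 0:
            raise ValueError(f"empty temperature series for ZCTA {self.zcta_id}")
        if not np.all(np.isfinite(self.tmean)):
            raise ValueError(f"non-finite temperatures in ZCTA {self.zcta_id}")
        day = self.dates.asi8 // 86_400_000_000_000
        if len(day) > 1 and not np.all(np.diff(day) == 1):
            raise ValueError(
                f"dates for ZCTA {self.zcta_id} must be consecutive calendar days"
            )
        self._day0 = int(day[0])

    def __len__(self) -> int:
        return len(self.tmean)

    def index_of(self, date) -> int:
        """Position of ``date`` in the series; raises ``KeyError`` if outside."""
        i = int(pd.Timestamp(date).value // 86_400_000_000_000) - self._day0
        if not 0 <= i < len(self.tmean):
            raise KeyError(date)
        return i


@dataclass(frozen=True)
class HeatWaveExposure:
    """Window heat-wave metrics attached to one ZCTA-day (the window end)."""

    zcta_id: str
    date: pd.Timestamp
    run_length: int
    aat: float

    @property
    def hw_ge2(self) -> bool:
        return self.run_length >= 2

    @property
    def hw_ge3(self) -> bool:
        return self.run_length >= 3

    @property
    def hw_eq4(self) -> bool:
        return self.run_length >= DEFAULT_WINDOW


def zcta_daily_series(
    grid_temps: pd.DataFrame,
    grid_map: pd.DataFrame,
    require_zctas=None,
) -> dict[str, ZctaTempSeries]:
    """Average gridded tmin/tmax to ZCTA daily mean temperature series.

    Parameters
    ----------
    grid_temps
        Columns ``point_id, date, tmin_c, tmax_c``; one row per grid
        point per day, covering every date for every point.
    grid_map
        Columns ``point_id, zcta_id`` assigning each grid point to the
        ZCTA whose polygon contains it.
    require_zctas
        Optional iterable of ZCTA ids that must be covered; a listed
        ZCTA with no mapped grid point is a hard error.

    Returns
    -------
    dict mapping zcta_id to :class:`ZctaTempSeries` (threshold not yet set).

    Notes
    -----
    The ZCTA daily mean is ``(mean(tmin) + mean(tmax)) / 2`` over the
    mapped points — an unweighted average, then the min/max midpoint.
    Missing point-days are a hard error: no imputation is attempted.
    """
    temps = grid_temps.copy()
    temps["date"] = pd.to_datetime(temps["date"])
    if (temps["tmin_c"] > temps["tmax_c"]).any():
        bad = temps.loc[temps["tmin_c"] > temps["tmax_c"], "point_id"].iloc[0]
        raise ValueError(f"tmin > tmax for grid point {bad}")

    known_points = set(temps["point_id"].unique())
    unknown = set(grid_map["point_id"]) - known_points
    if unknown:
        raise KeyError(
            f"grid map references point ids with no temperature record: "
            f"{sorted(unknown)[:5]}"
        )
    if require_zctas is not None:
        missing = set(require_zctas) - set(grid_map["zcta_id"])
        if missing:
            raise ValueError(
                f"no grid points mapped to ZCTA(s): {sorted(missing)[:5]}"
            )

    n_dates = temps["date"].nunique()
    per_point = temps.groupby("point_id")["date"].count()
    short = per_point[per_point != n_dates]
    if len(short):
        raise ValueError(
            f"grid point {short.index[0]} has {short.iloc[0]} dates, "
            f"expected {n_dates} (missing temperature records)"
        )

    merged = temps.merge(grid_map, on="point_id", how="inner")
    agg = (
        merged.groupby(["zcta_id", "date"])[["tmin_c", "tmax_c"]]
        .mean()
        .reset_index()
    )
    agg["tmean_c"] = (agg["tmin_c"] + agg["tmax_c"]) / 2.0

    out: dict[str, ZctaTempSeries] = {}
    for zcta, sub in agg.groupby("zcta_id", sort=True):
        sub = sub.sort_values("date")
        out[zcta] = ZctaTempSeries(
            zcta_id=zcta,
            dates=pd.DatetimeIndex(sub["date"]),
            tmean=sub["tmean_c"].to_numpy(),
        )
    return out


def hot_day_threshold(
    series: ZctaTempSeries | np.ndarray,
    percentile: float = DEFAULT_PERCENTILE,
) -> float:
    """Empirical hot-day threshold: a percentile of the full daily-mean series.

    Computed over *all* days of the series (all seasons, all years).
    When given a :class:`ZctaTempSeries` the result is also stored on
    ``series.threshold``.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie strictly between 0 and 100")
    values = series.tmean if isinstance(series, ZctaTempSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ValueError("cannot compute a threshold on an empty series")
    thr = float(np.quantile(values, percentile / 100.0, method=QUANTILE_METHOD))
    if isinstance(series, ZctaTempSeries):
        series.threshold = thr
    return thr


def window_run_length(window_temps, threshold: float) -> int:
    """Longest run of consecutive days strictly above ``threshold`` in a 4-day window."""
    w = np.asarray(window_temps, dtype=float)
    if w.shape != (DEFAULT_WINDOW,):
        raise ValueError(f"expected exactly {DEFAULT_WINDOW} window temperatures")
    hot = w > threshold  # ties at the threshold are not hot
    best = run = 0
    for h in hot:
        run = run + 1 if h else 0
        best = max(best, run)
    return best


def window_aat(window_temps, threshold: float) -> float:
    """Average degrees above threshold over the window, floored at zero.

    Days below the threshold contribute negative deviations to the
    window mean before the floor is applied.
    """
    w = np.asarray(window_temps, dtype=float)
    if w.shape != (DEFAULT_WINDOW,):
        raise ValueError(f"expected exactly {DEFAULT_WINDOW} window temperatures")
    return max(0.0, float(w.mean() - threshold))


def exposure_for_date(
    series: ZctaTempSeries,
    date,
    lag_start: int = 0,
    window: int = DEFAULT_WINDOW,
) -> HeatWaveExposure:
    """Heat-wave metrics for the window ending ``lag_start`` days before ``date``.

    The default window is lags 0-3: the day itself and the three
    preceding days.  A window reaching before the series start raises
    :class:`MissingExposureError`; callers exclude such records and
    count them in their exclusion logs.
    """
    if series.threshold is None:
        raise ValueError("series threshold not set; call hot_day_threshold first")
    end = series.index_of(date) - lag_start
    start = end - window + 1
    if start < 0 or end >= len(series):
        raise MissingExposureError(
            f"exposure window for {pd.Timestamp(date).date()} extends outside "
            f"the temperature series of ZCTA {series.zcta_id}"
        )
    temps = series.tmean[start : end + 1]
    return HeatWaveExposure(
        zcta_id=series.zcta_id,
        date=pd.Timestamp(date),
        run_length=window_run_length(temps, series.threshold),
        aat=window_aat(temps, series.threshold),
    )


def window_metrics(
    tmean: np.ndarray,
    threshold: float,
    lag_start: int = 0,
    window: int = DEFAULT_WINDOW,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Vectorized run-length and AAT for every complete window of a series.

    Returns ``(first, run_length, aat)`` where ``first`` is the index of
    the earliest day whose window (lags ``lag_start`` .. ``lag_start +
    window - 1``) lies within the series, and the two arrays cover days
    ``first .. n-1``.
    """
    t = np.asarray(tmean, dtype=float)
    n = len(t)
    first = window - 1 + lag_start
    if n <= first:
        return first, np.empty(0, dtype=np.int64), np.empty(0)
    hot = t > threshold
    # run of hot days ending at each day: distance to the last non-hot day
    pos = np.arange(n, dtype=np.int64)
    last_cold = np.maximum.accumulate(np.where(~hot, pos, -1))
    run_end = np.minimum(pos - last_cold, window)
    # run length within the window ending at day i - lag_start:
    # max over window days j of min(run_end[j], j - window_start + 1)
    offs = np.arange(window)
    idx = np.arange(first, n)[:, None] - lag_start - offs[None, ::-1]
    capped = np.minimum(run_end[idx], offs[None, :] + 1)
    rl = capped.max(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(t)])
    ends = np.arange(first, n) - lag_start
    wmean = (csum[ends + 1] - csum[ends + 1 - window]) / window
    aat = np.maximum(0.0, wmean - threshold)
    return first, rl, aat


def exposure_table(
    series_by_zcta: dict[str, ZctaTempSeries],
    lag_start: int = 0,
    window: int = DEFAULT_WINDOW,
    percentile: float = DEFAULT_PERCENTILE,
) -> pd.DataFrame:
    """Vectorized heat-wave metrics for every complete ZCTA-day window.

    Thresholds are computed (and stored) for any series lacking one.
    Returns a long table ``zcta_id, date, tmean_c, run_length, aat,
    hw_ge2, hw_ge3, hw_eq4`` covering the dates whose window lies
    within each series.
    """
    frames = []
    for zcta, s in series_by_zcta.items():
        if s.threshold is None:
            hot_day_threshold(s, percentile)
        first, rl, aat = window_metrics(s.tmean, s.threshold, lag_start, window)
        if len(rl) == 0:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "zcta_id": zcta,
                    "date": s.dates[first:],
                    "tmean_c": s.tmean[first:],
                    "run_length": rl,
                    "aat": aat,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=["zcta_id", "date", "tmean_c", "run_length", "aat",
                     "hw_ge2", "hw_ge3", "hw_eq4"]
        )
    out = pd.concat(frames, ignore_index=True)
    out["hw_ge2"] = out["run_length"] >= 2
    out["hw_ge3"] = out["run_length"] >= 3
    out["hw_eq4"] = out["run_length"] >= window
    return out
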