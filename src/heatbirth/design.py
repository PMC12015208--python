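"""Time-stratified case-crossover strata for birth-day analyses.

The event day is the birth day; referent days are every other day in
the same calendar month falling on the same day of week (three or four
of them, by calendar arithmetic).  Comparing exposure on the event day
with exposure on the referent days within the same person removes all
time-invariant confounding; matching on month and weekday controls
season and day-of-week patterns.  The analysis is restricted to the
warm season (May 1 - September 30 by default), when heat waves occur.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
import pandas as pd

__all__ = [
    "WARM_MONTHS",
    "classify_outcome",
    "in_warm_season",
    "referent_days",
    "assemble_strata",
]

WARM_MONTHS = (5, 9)  # inclusive month range: May 1 through September 30

#: Gestational-week ranges (completed weeks, inclusive) defining the outcomes.
OUTCOME_WEEKS = {"PTB": (28, 36), "ETB": (37, 38)}


def classify_outcome(ga_weeks: int) -> str:
    """Outcome class of a birth: PTB (28-36 wk), ETB (37-38 wk), or ``other``."""
    for name, (lo, hi) in OUTCOME_WEEKS.items():
        if lo <= ga_weeks <= hi:
            return name
    return "other"


def in_warm_season(date, months: tuple[int, int] = WARM_MONTHS) -> bool:
    """True if ``date`` falls in the warm season (month range, inclusive)."""
    m = pd.Timestamp(date).month
    return months[0] <= m <= months[1]


def referent_days(event_date) -> list[pd.Timestamp]:
    """All other days in the event's month sharing its day of week.

    Every calendar month has four or five occurrences of each weekday,
    so there are always three or four referents.  The relation is
    symmetric: d' is a referent of d iff d is a referent of d'.
    """
    d = pd.Timestamp(event_date)
    offsets = np.arange(-4, 5) * 7
    cand = d + pd.to_timedelta(offsets, unit="D")
    keep = (cand.month == d.month) & (cand.year == d.year) & (cand != d)
    return list(cand[keep])


def _stratum_days(event_dates: pd.Series) -> pd.DataFrame:
    """Long table of (row index, day, is_case) for event + referent days."""
    ev = pd.to_datetime(event_dates)
    parts = []
    for k in range(-4, 5):
        cand = ev + pd.Timedelta(days=7 * k)
        ok = (cand.dt.month == ev.dt.month) & (cand.dt.year == ev.dt.year)
        parts.append(
            pd.DataFrame(
                {"_row": ev.index[ok], "date": cand[ok], "is_case": k == 0}
            )
        )
    return pd.concat(parts, ignore_index=True)


def assemble_strata(
    births: pd.DataFrame,
    exposures: pd.DataFrame,
    adjustments: pd.DataFrame | None,
    outcome: str,
    warm_months: tuple[int, int] = WARM_MONTHS,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build case-crossover strata for one outcome.

    Parameters
    ----------
    births
        Birth records with columns ``birth_id, state, zcta_id,
        birth_date, ga_weeks`` (plus any subgroup columns, carried
        through unchanged).
    exposures
        Heat-wave metric table from :func:`heatbirth.exposure.exposure_table`
        (``zcta_id, date, run_length, aat, hw_ge2, hw_ge3, hw_eq4``).
    adjustments
        Daily risk-set adjustment table with columns ``zcta_id, date,
        w_i`` (see :mod:`heatbirth.riskset`); ``None`` to omit.
    outcome
        ``"PTB"`` or ``"ETB"``.

    Returns
    -------
    strata : DataFrame
        Long format, one row per stratum-day: ``birth_id, date,
        is_case`` plus exposure metrics, ``w_adjust`` and the carried
        birth columns.  Strata are contiguous and sorted by birth_id.
    exclusions : dict
        Counts of excluded births by reason (``not_case``,
        ``outside_warm_season``, ``missing_exposure``,
        ``missing_adjustment``).

    Notes
    -----
    Strata in which the covariates are constant across days contribute
    nothing to the conditional likelihood but are retained here; the
    fitting step counts them separately.  Births whose stratum has any
    day with a missing exposure or adjustment value are excluded whole
    (a stratum must be complete to be comparable) and tallied.
    """
    if outcome not in OUTCOME_WEEKS:
        raise ValueError(f"unknown outcome {outcome!r}")
    excl: Counter[str] = Counter()

    b = births.reset_index(drop=True).copy()
    b["birth_date"] = pd.to_datetime(b["birth_date"])
    lo, hi = OUTCOME_WEEKS[outcome]
    is_case = b["ga_weeks"].between(lo, hi)
    excl["not_case"] = int((~is_case).sum())
    b = b[is_case]
    warm = b["birth_date"].dt.month.between(*warm_months)
    excl["outside_warm_season"] = int((~warm).sum())
    b = b[warm]
    if b.empty:
        cols = ["birth_id", "date", "is_case", "run_length", "aat",
                "hw_ge2", "hw_ge3", "hw_eq4", "w_adjust"]
        return pd.DataFrame(columns=cols), dict(excl)

    days = _stratum_days(b["birth_date"])
    days = days.merge(
        b.drop(columns=["birth_date"]), left_on="_row", right_index=True
    )

    # attach day-level covariates by integer (zcta, day) key lookup —
    # equivalent to a left merge on (zcta_id, date) but far cheaper
    zcta_cats = pd.Index(exposures["zcta_id"].unique())

    def _keys(zcta, dates_col):
        zc = zcta_cats.get_indexer(zcta).astype(np.int64)
        day_num = pd.to_datetime(dates_col).astype("int64") // 86_400_000_000_000
        key = zc * (1 << 24) + day_num.to_numpy()
        key[zc < 0] = -1  # ZCTA with no exposure data at all
        return key

    day_keys = _keys(days["zcta_id"], days["date"])
    exp_cols = [c for c in exposures.columns if c not in ("zcta_id", "date")]
    exp_index = pd.Index(_keys(exposures["zcta_id"], exposures["date"]))
    pos = exp_index.get_indexer(day_keys)
    found = (pos >= 0) & (day_keys >= 0)
    for c in exp_cols:
        vals = exposures[c].to_numpy()[pos]
        days[c] = np.where(found, vals, np.nan)

    bad_exp = days.loc[~found, "_row"].unique()
    excl["missing_exposure"] = len(bad_exp)
    days = days[~days["_row"].isin(bad_exp)]

    if adjustments is not None:
        adj_index = pd.Index(_keys(adjustments["zcta_id"], adjustments["date"]))
        pos = adj_index.get_indexer(_keys(days["zcta_id"], days["date"]))
        w = np.where(pos >= 0, adjustments["w_i"].to_numpy()[pos], np.nan)
        days["w_adjust"] = w
        bad_adj = days.loc[~np.isfinite(w), "_row"].unique()
        excl["missing_adjustment"] = len(bad_adj)
        days = days[~days["_row"].isin(bad_adj)]

    days = days.sort_values(["_row", "date"]).drop(columns=["_row"])
    front = ["birth_id", "date", "is_case"]
    days = days[front + [c for c in days.columns if c not in front]]
    return days.reset_index(drop=True), dict(excl)
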