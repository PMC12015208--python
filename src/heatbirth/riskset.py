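"""Daily pregnancy risk-set adjustment for case-crossover birth analyses.

Within a case-crossover stratum the pool of pregnancies at risk — and
how far along they are — changes from day to day (conception
seasonality, secular trends, digit preference in gestational-age
reporting).  That shifts the baseline probability of birth across the
event and referent days and can confound acute exposure effects.  The
adjustment covariate used here is the average probability of birth on
each day among ongoing pregnancies in the ZCTA:

    W_i = sum_g Z_ig * W_g / Z_i

where ``Z_ig`` counts ongoing pregnancies at gestational week ``g`` on
day ``i`` (``g`` running over the outcome's risk range: weeks 28-36
for preterm, 37-38 for early term), ``Z_i`` counts all ongoing
pregnancies on day ``i``, and ``W_g`` is the probability of birth at
week ``g`` among pregnancies reaching week ``g`` (a discrete hazard
estimated from all births of the state over the study period).

Conventions: pregnancy start is ``birth_date - 7 * ga_weeks`` days; a
pregnancy is ongoing on day ``i`` iff ``start <= i < birth_date`` (the
newborn is an event, not at risk, on its birth day); the gestational
week on day ``i`` is ``floor((i - start) / 7)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import OUTCOME_WEEKS

__all__ = [
    "gestational_week_on_day",
    "birth_week_hazard",
    "adjustment_table",
    "adjustment_series",
]

_DAY_NS = 86_400_000_000_000

#: Latest plausible gestation (completed weeks); days closer than this to
#: the end of the birth data have right-truncated risk sets.
MAX_GA_WEEKS = 45


def _day_number(dates) -> np.ndarray:
    return np.asarray(pd.to_datetime(dates)).astype("datetime64[ns]").astype(np.int64) // _DAY_NS


def gestational_week_on_day(birth_date, ga_weeks: int, day) -> int | None:
    """Completed gestational week of a pregnancy on calendar day ``day``.

    Returns ``None`` if the pregnancy is not ongoing on that day (it
    has not started, or the birth has already occurred — including the
    birth day itself).
    """
    b = int(_day_number([birth_date])[0])
    i = int(_day_number([day])[0])
    start = b - 7 * int(ga_weeks)
    if not (start <= i < b):
        return None
    return (i - start) // 7


def birth_week_hazard(all_births: pd.DataFrame, method: str = "hazard") -> pd.DataFrame:
    """Week-specific birth probabilities W_g from a table of births.

    Parameters
    ----------
    all_births
        Birth records (all outcome classes — the risk set uses every
        birth, not just cases) with a ``ga_weeks`` column.  Callers
        wanting state-specific hazards pass one state's births.
    method
        ``"hazard"`` (default): W_g = births at week g / births at
        week >= g, the discrete hazard among pregnancies reaching g.
        ``"marginal"``: W_g = births at week g / all births.

    Returns
    -------
    DataFrame with columns ``ga_weeks, w_g, n_births, n_at_risk``
    covering every week from the minimum to the maximum observed.
    """
    if len(all_births) == 0:
        raise ValueError("cannot estimate week hazards from an empty birth table")
    ga = all_births["ga_weeks"].to_numpy()
    weeks = np.arange(ga.min(), ga.max() + 1)
    counts = np.array([(ga == g).sum() for g in weeks], dtype=np.int64)
    at_risk = counts[::-1].cumsum()[::-1]
    if method == "hazard":
        w = counts / at_risk  # at_risk > 0 on [min, max] by construction
    elif method == "marginal":
        w = counts / len(ga)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {"ga_weeks": weeks, "w_g": w, "n_births": counts, "n_at_risk": at_risk}
    )


def adjustment_table(
    all_births: pd.DataFrame,
    dates,
    outcome: str,
    week_hazard: pd.DataFrame,
    return_zig: bool = False,
):
    """Daily risk-set adjustment W_i for every ZCTA over a date range.

    Parameters
    ----------
    all_births
        All births (every outcome class) with columns ``zcta_id,
        birth_date, ga_weeks``.
    dates
        Contiguous daily ``DatetimeIndex`` (or convertible) over which
        to compute the adjustment.
    outcome
        ``"PTB"`` or ``"ETB"`` — selects the risk-week range summed in
        the numerator.
    week_hazard
        Output of :func:`birth_week_hazard`; must cover the risk range.
    return_zig
        Also return the dense at-risk count array ``Z[z, d, g]``
        (ZCTA x day x risk week) for auditing.

    Returns
    -------
    DataFrame ``zcta_id, date, outcome, z_total, w_i, boundary_flag``.
    ``w_i`` is NaN where no pregnancy is ongoing (``z_total`` = 0);
    ``boundary_flag`` marks days within 45 weeks of the last observed
    birth, whose risk sets may be right-truncated (future births that
    would have been ongoing are not yet in the data).
    """
    if outcome not in OUTCOME_WEEKS:
        raise ValueError(f"unknown outcome {outcome!r}")
    g_lo, g_hi = OUTCOME_WEEKS[outcome]
    wh = week_hazard.set_index("ga_weeks")["w_g"]
    missing = [g for g in range(g_lo, g_hi + 1) if g not in wh.index]
    if missing:
        raise ValueError(
            f"week hazard table lacks risk-range weeks {missing} for {outcome}"
        )

    dates = pd.DatetimeIndex(pd.to_datetime(dates))
    day = _day_number(dates)
    if len(day) > 1 and not np.all(np.diff(day) == 1):
        raise ValueError("dates must be a contiguous daily range")
    d0, n_days = int(day[0]), len(day)

    zcta_codes, zcta_index = pd.factorize(all_births["zcta_id"], sort=True)
    n_z = len(zcta_index)
    birth = _day_number(all_births["birth_date"])
    ga = all_births["ga_weeks"].to_numpy(dtype=np.int64)
    start = birth - 7 * ga

    # Z_i: ongoing on day i <=> start <= i < birth; count by sorted search
    z_total = np.zeros((n_z, n_days), dtype=np.int64)
    for z in range(n_z):
        m = zcta_codes == z
        s = np.sort(start[m])
        b = np.sort(birth[m])
        z_total[z] = np.searchsorted(s, day, side="right") - np.searchsorted(
            b, day, side="right"
        )

    # Numerator sum_g Z_ig W_g: week g of a pregnancy spans exactly the 7
    # days [start + 7g, start + 7g + 6], all ongoing when g < ga_weeks.
    numer = np.zeros(n_z * n_days)
    zig = (
        np.zeros((n_z, n_days, g_hi - g_lo + 1), dtype=np.int64)
        if return_zig
        else None
    )
    offsets = np.arange(7)
    for g in range(g_lo, g_hi + 1):
        s_g = start + 7 * g
        # prune pregnancies whose week-g span cannot intersect the window
        sel = (ga > g) & (s_g >= d0 - 6) & (s_g < d0 + n_days)
        if not sel.any():
            continue
        s_g = s_g[sel]
        z_g = zcta_codes[sel]
        days_g = s_g[:, None] + offsets[None, :]
        rel = days_g - d0
        ok = (rel >= 0) & (rel < n_days)
        flat = np.broadcast_to(z_g[:, None], rel.shape)[ok] * n_days + rel[ok]
        numer += float(wh.loc[g]) * np.bincount(flat, minlength=numer.size)
        if zig is not None:
            n_weeks = g_hi - g_lo + 1
            zig.reshape(-1)[:] += np.bincount(
                flat * n_weeks + (g - g_lo), minlength=zig.size
            )

    with np.errstate(invalid="ignore", divide="ignore"):
        w_i = np.where(z_total.reshape(-1) > 0,
                       numer / np.maximum(z_total.reshape(-1), 1), np.nan)

    boundary = day > birth.max() - 7 * MAX_GA_WEEKS
    out = pd.DataFrame(
        {
            "zcta_id": np.repeat(zcta_index.to_numpy(), n_days),
            "date": np.tile(dates.to_numpy(), n_z),
            "outcome": outcome,
            "z_total": z_total.reshape(-1),
            "w_i": w_i,
            "boundary_flag": np.tile(boundary, n_z),
        }
    )
    if return_zig:
        return out, zig
    return out


def adjustment_series(
    all_births: pd.DataFrame,
    zcta_id,
    dates,
    outcome: str,
    week_hazard: pd.DataFrame,
) -> pd.DataFrame:
    """W_i series for a single ZCTA (see :func:`adjustment_table`)."""
    sub = all_births[all_births["zcta_id"] == zcta_id]
    if sub.empty:
        raise ValueError(f"no births recorded in ZCTA {zcta_id}")
    return adjustment_table(sub, dates, outcome, week_hazard)
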