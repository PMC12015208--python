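"""Synthetic temperature, population and birth data with a known heat effect.

Real vital records are confidential, so every stage of the pipeline is
exercised on simulated data in which the true effect of heat on the
daily birth hazard is set by configuration and can be recovered.

The generator emulates the structure of the real inputs:

* **Temperature** — per grid point, a seasonal sinusoid plus a
  stationary AR(1) process and a ZCTA-specific (urban) offset; daily
  minimum/maximum are emitted symmetrically around the latent mean.
* **Population** — pregnancies per ZCTA with seasonally varying
  conception dates and multinomial maternal age / education groups;
  per-ZCTA Social Deprivation Index (1-100 centile) and impervious
  land-cover fraction, optionally correlated with the ZCTA's urban
  temperature offset.
* **Births** — each pregnancy is simulated day by day from week 20:
  the probability of birth on a day at gestational week ``g`` is the
  baseline daily hazard (from a weekly discrete-hazard table) times
  ``exp(beta * AAT)`` on that day, with AAT the same 4-day
  average-degrees-above-threshold metric the analysis measures, and
  ``beta`` the (possibly subgroup-specific) log odds ratio per deg C.
  The multiplier applies during the outcome-relevant weeks (28-38 by
  default).  Pregnancies reaching week 45 undeliver are forced to
  deliver (and counted).

The temperature series is generated with ~11 months of padding on both
sides of the analysis years so that every analysis day has a complete
risk set (all pregnancies ongoing on it are conceived, and deliver,
inside the simulated window) and a complete exposure window.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exposure import ZctaTempSeries, hot_day_threshold, window_metrics

__all__ = ["SimConfig", "SimData", "simulate", "gen_temperature",
           "gen_population", "gen_births", "write_inputs"]

#: Days of padding around the analysis years: longer than the longest
#: simulated gestation (45 weeks = 315 days) plus the exposure window.
PAD_DAYS = 330

#: Weekly probability of birth at week g among pregnancies reaching g
#: (discrete hazard).  Chosen to give roughly 8% preterm (28-36 wk) and
#: 22% early term (37-38 wk) births, in line with US population figures.
DEFAULT_WEEK_HAZARD: dict[int, float] = {
    20: 0.0004, 21: 0.0005, 22: 0.0006, 23: 0.0008,
    24: 0.0010, 25: 0.0013, 26: 0.0016, 27: 0.0020,
    28: 0.0025, 29: 0.0030, 30: 0.0040, 31: 0.0050, 32: 0.0070,
    33: 0.0090, 34: 0.0120, 35: 0.0160, 36: 0.0220,
    37: 0.1000, 38: 0.1600,
    39: 0.3400, 40: 0.5000, 41: 0.6000, 42: 0.7000, 43: 0.7500, 44: 0.8500,
}
FORCED_WEEK = 45  # still undelivered after week 44 -> forced birth


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a temperate mid-latitude study region over three
    warm seasons at a scale that runs in minutes on one CPU.
    """

    n_states: int = 4
    zctas_per_state: int = 25
    pregnancies_per_zcta: int = 2000  # conceived over the whole window
    years: int = 3                    # analysis calendar years
    start_year: int = 2001
    seed: int = 0
    # temperature process (deg C)
    annual_mean_c: float = 17.0
    seasonal_amplitude_c: float = 9.0
    seasonal_peak_doy: int = 197      # mid-July peak
    ar1_rho: float = 0.80
    innovation_sd_c: float = 1.6
    urban_offset_sd_c: float = 1.0
    diurnal_half_range_c: float = 5.0
    points_per_zcta: int = 4
    point_noise_sd_c: float = 0.5
    # population
    conception_seasonality: float = 0.10   # relative amplitude
    conception_peak_doy: int = 250         # early-September conception peak
    age_props: tuple[float, float, float] = (0.31, 0.52, 0.17)
    edu_props: tuple[float, float, float] = (0.25, 0.30, 0.45)
    edu_missing_states: tuple[str, ...] = ()
    sdi_temp_corr: float = 0.4
    landcover_temp_corr: float = 0.5
    # outcome model
    week_hazard: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_WEEK_HAZARD)
    )
    effect_log_or: float = float(np.log(1.05))  # per deg C AAT
    effect_by_subgroup: dict[str, dict[str, float]] | None = None
    effect_weeks: tuple[int, int] = (28, 38)

    def state_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_states)]


AGE_LEVELS = ("<25", "25-34", "35+")
EDU_LEVELS = ("<HS", "HS/GED", ">HS")


@dataclass
class SimData:
    """Generated study inputs plus the simulation truth."""

    births: pd.DataFrame
    pregnancies: pd.DataFrame
    area: pd.DataFrame
    grid_temps: pd.DataFrame | None
    grid_map: pd.DataFrame
    zcta_series: dict[str, ZctaTempSeries]
    zcta_states: dict[str, str]
    truth: dict


def _temp_dates(config: SimConfig) -> pd.DatetimeIndex:
    start = pd.Timestamp(f"{config.start_year}-01-01") - pd.Timedelta(days=PAD_DAYS)
    end = pd.Timestamp(f"{config.start_year + config.years - 1}-12-31") + pd.Timedelta(
        days=PAD_DAYS
    )
    return pd.date_range(start, end, freq="D")


def _latent_series(config: SimConfig, rng: np.random.Generator):
    """Latent ZCTA daily mean temperatures: seasonal + offset + AR(1)."""
    dates = _temp_dates(config)
    n_z = config.n_states * config.zctas_per_state
    doy = dates.dayofyear.to_numpy()
    seasonal = config.annual_mean_c + config.seasonal_amplitude_c * np.sin(
        2 * np.pi * (doy - config.seasonal_peak_doy) / 365.25 + np.pi / 2
    )
    offsets = rng.normal(0.0, config.urban_offset_sd_c, size=n_z)
    burn = 100
    eps = rng.normal(0.0, config.innovation_sd_c, size=(n_z, len(dates) + burn))
    ar = lfilter([1.0], [1.0, -config.ar1_rho], eps, axis=1)[:, burn:]
    latent = seasonal[None, :] + offsets[:, None] + ar
    zcta_ids = [
        f"{s}-Z{i + 1:03d}"
        for s in config.state_ids()
        for i in range(config.zctas_per_state)
    ]
    states = {z: z.split("-")[0] for z in zcta_ids}
    return dates, latent, zcta_ids, states, offsets


def gen_temperature(config: SimConfig, rng: np.random.Generator | None = None):
    """Emit gridded daily tmin/tmax and the grid-point -> ZCTA map.

    Each ZCTA holds ``points_per_zcta`` grid points sharing the ZCTA's
    latent series plus independent point-level noise; tmin/tmax are the
    latent mean -/+ the diurnal half-range.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dates, latent, zcta_ids, _, _ = _latent_series(config, rng)
    rows_t, rows_m = [], []
    for zi, zcta in enumerate(zcta_ids):
        for p in range(config.points_per_zcta):
            pid = f"{zcta}-P{p + 1}"
            noise = (
                rng.normal(0.0, config.point_noise_sd_c, size=len(dates))
                if config.point_noise_sd_c > 0
                else 0.0
            )
            tm = latent[zi] + noise
            rows_t.append(
                pd.DataFrame(
                    {
                        "point_id": pid,
                        "date": dates,
                        "tmin_c": tm - config.diurnal_half_range_c,
                        "tmax_c": tm + config.diurnal_half_range_c,
                    }
                )
            )
            rows_m.append((pid, zcta))
    grid_temps = pd.concat(rows_t, ignore_index=True)
    grid_map = pd.DataFrame(rows_m, columns=["point_id", "zcta_id"])
    return grid_temps, grid_map


def gen_population(
    config: SimConfig,
    rng: np.random.Generator,
    dates: pd.DatetimeIndex,
    zcta_ids: list[str],
    states: dict[str, str],
    offsets: np.ndarray,
):
    """Pregnancy table (conception dates, subgroups) and area attributes."""
    n_z = len(zcta_ids)
    # conception window: every ongoing pregnancy on an analysis day is
    # conceived, and delivers, inside the simulated temperature window
    conc_dates = dates[: len(dates) - PAD_DAYS]
    doy = conc_dates.dayofyear.to_numpy()
    w = 1.0 + config.conception_seasonality * np.cos(
        2 * np.pi * (doy - config.conception_peak_doy) / 365.25
    )
    w = w / w.sum()
    n = config.pregnancies_per_zcta
    # inverse-CDF sampling of conception days (faster than choice with p)
    conc_idx = np.searchsorted(np.cumsum(w), rng.random(n_z * n), side="right")
    conc_idx = np.minimum(conc_idx, len(conc_dates) - 1)
    zcta_codes = np.repeat(np.arange(n_z), n)
    age_codes = np.searchsorted(
        np.cumsum(config.age_props), rng.random(n_z * n), side="right"
    ).clip(0, 2)
    edu_codes = np.searchsorted(
        np.cumsum(config.edu_props), rng.random(n_z * n), side="right"
    ).clip(0, 2)
    state_of_zcta = np.array([states[z] for z in zcta_ids], dtype=object)
    state_cats = pd.CategoricalDtype(sorted(set(state_of_zcta)))
    state_code_of_zcta = pd.Categorical(state_of_zcta, dtype=state_cats).codes
    edu_cats = list(EDU_LEVELS) + ["missing"]
    edu = pd.Categorical.from_codes(edu_codes, categories=edu_cats)
    preg = pd.DataFrame(
        {
            "pregnancy_id": np.arange(n_z * n),
            "zcta_id": pd.Categorical.from_codes(
                zcta_codes, categories=zcta_ids
            ),
            "state": pd.Categorical.from_codes(
                state_code_of_zcta[zcta_codes], dtype=state_cats
            ),
            "conception_date": conc_dates[conc_idx],
            "age_group": pd.Categorical.from_codes(
                age_codes, categories=list(AGE_LEVELS)
            ),
            "edu_group": edu,
        }
    )
    if config.edu_missing_states:
        m = preg["state"].isin(config.edu_missing_states)
        preg.loc[m, "edu_group"] = "missing"

    # area attributes, rank-correlated with the urban temperature offset
    z_off = (offsets - offsets.mean()) / (offsets.std() + 1e-12)
    mix = lambda c: c * z_off + np.sqrt(1 - c**2) * rng.normal(size=n_z)
    sdi_latent = mix(config.sdi_temp_corr)
    sdi = (pd.Series(sdi_latent).rank(method="first") / n_z * 100).clip(1, 100)
    lc_latent = -1.1 + 2.28 * mix(config.landcover_temp_corr)
    impervious = 1.0 / (1.0 + np.exp(-lc_latent))
    area = pd.DataFrame(
        {
            "zcta_id": zcta_ids,
            "sdi_score": np.ceil(sdi).astype(int),
            "impervious_frac": impervious,
        }
    )
    return preg, area


def _daily_hazard(config: SimConfig) -> np.ndarray:
    """Daily birth probability by day-offset 140..314 from conception."""
    offs = np.arange(140, 7 * FORCED_WEEK)
    weekly = np.array([config.week_hazard[g] for g in offs // 7])
    return 1.0 - (1.0 - weekly) ** (1.0 / 7.0)


def _pregnancy_betas(config: SimConfig, preg: pd.DataFrame) -> np.ndarray:
    beta = np.full(len(preg), config.effect_log_or)
    if config.effect_by_subgroup:
        for col, table in config.effect_by_subgroup.items():
            for level, b in table.items():
                beta[(preg[col] == level).to_numpy()] = b
    return beta


def gen_births(
    pregnancies: pd.DataFrame,
    aat: np.ndarray,
    aat_dates: pd.DatetimeIndex,
    zcta_ids: list[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate birth days given daily heat-wave exposure.

    ``aat`` is a (n_zcta, n_days) array of average-degrees-above-
    threshold aligned with ``aat_dates``, in the same ZCTA order as
    ``zcta_ids``.
    """
    day0 = aat_dates[0]
    zmap = {z: i for i, z in enumerate(zcta_ids)}
    zidx = pregnancies["zcta_id"].map(zmap).to_numpy()
    conc_rel = (
        (pd.to_datetime(pregnancies["conception_date"]) - day0).dt.days.to_numpy()
    )
    beta = _pregnancy_betas(config, pregnancies)
    h = _daily_hazard(config)
    offs = np.arange(140, 7 * FORCED_WEEK)
    eff = (offs // 7 >= config.effect_weeks[0]) & (offs // 7 <= config.effect_weeks[1])

    # The daily Bernoulli birth process is simulated in three phases.
    # Outside the effect weeks the hazard does not depend on exposure, so
    # the birth day there is drawn from the exact first-passage
    # distribution of the fixed daily hazards (inverse CDF — identical in
    # law to day-by-day coin flips); only the effect weeks need the full
    # per-day exposure-dependent simulation.
    i_mid = np.flatnonzero(eff)
    m0, m1 = (i_mid[0], i_mid[-1] + 1) if len(i_mid) else (len(offs), len(offs))
    if len(i_mid) and not np.all(np.diff(i_mid) == 1):
        raise ValueError("effect_weeks must be a contiguous week range")

    def _first_passage(hazards):
        """pmf over birth days and survival probability for fixed hazards."""
        s = np.cumprod(1.0 - hazards)
        pmf = hazards * np.r_[1.0, s[:-1]]
        return np.cumsum(pmf), (s[-1] if len(s) else 1.0)

    cdf_pre, _ = _first_passage(h[:m0])
    cdf_post, _ = _first_passage(h[m1:])

    n = len(pregnancies)
    birth_off = np.full(n, -1, dtype=np.int64)

    if m0 > 0:
        u = rng.random(n)
        born = u < cdf_pre[-1]
        birth_off[born] = offs[0] + np.searchsorted(cdf_pre, u[born], side="right")

    alive = birth_off < 0
    idx_alive = np.flatnonzero(alive)
    h_mid = h[m0:m1].astype(np.float32)
    # few distinct effect sizes: precompute the hazard multiplier
    # exp(beta * AAT) on the (effect, zcta, day) grid once
    u_beta, beta_idx = np.unique(beta, return_inverse=True)
    mult = np.exp(u_beta[:, None, None] * aat[None, :, :]).astype(np.float32)
    chunk = 16384
    for lo in range(0, len(idx_alive), chunk):
        sel = idx_alive[lo : lo + chunk]
        day_idx = conc_rel[sel, None] + offs[None, m0:m1]
        if len(sel) and (day_idx.min() < 0 or day_idx.max() >= aat.shape[1]):
            raise ValueError("pregnancy window extends outside the exposure series")
        p = mult[beta_idx[sel, None], zidx[sel, None], day_idx]
        p *= h_mid[None, :]
        np.minimum(p, np.float32(0.99), out=p)
        hit = rng.random(p.shape, dtype=np.float32) < p
        first = hit.argmax(axis=1)
        any_hit = hit.any(axis=1)
        birth_off[sel[any_hit]] = offs[0] + m0 + first[any_hit]

    alive = birth_off < 0
    idx_alive = np.flatnonzero(alive)
    forced = 0
    if len(idx_alive):
        u = rng.random(len(idx_alive))
        born = u < (cdf_post[-1] if len(cdf_post) else 0.0)
        birth_off[idx_alive[born]] = (
            offs[0] + m1 + np.searchsorted(cdf_post, u[born], side="right")
        )
        forced = int((~born).sum())
        birth_off[idx_alive[~born]] = 7 * FORCED_WEEK

    births = pd.DataFrame(
        {
            "birth_id": pregnancies["pregnancy_id"].to_numpy(),
            "state": pregnancies["state"].array,
            "zcta_id": pregnancies["zcta_id"].array,
            "birth_date": pd.to_datetime(pregnancies["conception_date"])
            + pd.to_timedelta(birth_off, unit="D"),
            "ga_weeks": birth_off // 7,
            "age_group": pregnancies["age_group"].array,
            "edu_group": pregnancies["edu_group"].array,
        }
    )
    births.attrs["n_forced_week45"] = forced
    return births


def simulate(config: SimConfig, emit_grid: bool = True) -> SimData:
    """Run the full generator and return every pipeline input.

    With ``emit_grid=False`` the per-point grid table is skipped (the
    ZCTA series are used directly); exposure metrics computed from the
    emitted grid with the default point noise match the latent ones up
    to the point-level measurement noise.
    """
    rng = np.random.default_rng(config.seed)
    dates, latent, zcta_ids, states, offsets = _latent_series(config, rng)
    series: dict[str, ZctaTempSeries] = {}
    aat = np.zeros_like(latent)
    first = None
    for i, z in enumerate(zcta_ids):
        s = ZctaTempSeries(z, dates, latent[i])
        hot_day_threshold(s)
        series[z] = s
        f, _, a = window_metrics(latent[i], s.threshold)
        aat[i, f:] = a
        first = f
    # days before the first complete window keep aat 0; pregnancies never
    # reach the effect weeks there (padding exceeds the window length)

    preg, area = gen_population(config, rng, dates, zcta_ids, states, offsets)
    births = gen_births(preg, aat, dates, zcta_ids, config, rng)

    grid_temps, grid_map = None, pd.DataFrame(
        {"point_id": [f"{z}-P1" for z in zcta_ids], "zcta_id": zcta_ids}
    )
    if emit_grid:
        grid_rng = np.random.default_rng(rng.integers(2**31))
        grid_temps, grid_map = gen_temperature(config, grid_rng)

    truth = {
        "seed": config.seed,
        "effect_log_or": config.effect_log_or,
        "effect_by_subgroup": config.effect_by_subgroup,
        "effect_weeks": list(config.effect_weeks),
        "n_pregnancies": len(preg),
        "n_forced_week45": births.attrs["n_forced_week45"],
        "analysis_years": [config.start_year, config.start_year + config.years - 1],
    }
    return SimData(
        births=births,
        pregnancies=preg,
        area=area,
        grid_temps=grid_temps,
        grid_map=grid_map,
        zcta_series=series,
        zcta_states=states,
        truth=truth,
    )


def write_inputs(data: SimData, outdir) -> None:
    """Write the generated tables as the delimited files the CLI consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data.births.to_csv(out / "births.csv", index=False)
    data.area.to_csv(out / "area.csv", index=False)
    data.grid_map.to_csv(out / "grid_map.csv", index=False)
    if data.grid_temps is not None:
        data.grid_temps.to_csv(out / "grid_temps.csv", index=False)
    else:
        rows = []
        for z, s in data.zcta_series.items():
            rows.append(
                pd.DataFrame(
                    {
                        "point_id": f"{z}-P1",
                        "date": s.dates,
                        "tmin_c": s.tmean - 5.0,
                        "tmax_c": s.tmean + 5.0,
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(out / "grid_temps.csv", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(data.truth, fh, indent=2, default=str)
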