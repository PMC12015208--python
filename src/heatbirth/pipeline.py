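"""End-to-end stratified case-crossover analysis.

For each outcome x stratification variable x stratum level x state x
heat-wave definition, the pipeline assembles case-crossover strata,
fits conditional logistic regression (heat-wave exposure plus the
daily pregnancy risk-set adjustment W_i), pools the state estimates by
inverse-variance weighting, and tests heterogeneity across stratum
levels.  Fits are always per state, pooled afterwards; never a single
pooled mega-fit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .design import assemble_strata, WARM_MONTHS
from .exposure import (
    DEFAULT_PERCENTILE,
    DEFAULT_WINDOW,
    exposure_table,
    zcta_daily_series,
)
from .inference import fit_clogit
from .pooling import heterogeneity_wald, heterogeneity_z, ivw_pool
from .riskset import adjustment_table, birth_week_hazard

__all__ = ["AnalysisConfig", "AnalysisResult", "run_analysis", "summarize"]

log = logging.getLogger("heatbirth")

#: exposure covariate column per heat-wave definition
HW_COLUMNS = {"aat": "aat", "ge2": "hw_ge2", "ge3": "hw_ge3", "eq4": "hw_eq4"}

STRAT_LEVELS = {
    "none": ["all"],
    "age": ["<25", "25-34", "35+"],
    "education": ["<HS", "HS/GED", ">HS"],
    "sdi": ["low", "high"],
    "landcover": ["<25%", "25-66%", ">66%"],
}


@dataclass
class AnalysisConfig:
    """Settings of a stratified case-crossover analysis."""

    outcomes: tuple[str, ...] = ("PTB", "ETB")
    hw_defs: tuple[str, ...] = ("aat", "ge2", "ge3", "eq4")
    strat_vars: tuple[str, ...] = ("none",)
    warm_months: tuple[int, int] = WARM_MONTHS
    window_lag_start: int = 0
    window_length: int = DEFAULT_WINDOW
    threshold_percentile: float = DEFAULT_PERCENTILE
    boundary_policy: str = "flag"  # flag | exclude | ignore
    sdi_cut: float = 70.0
    landcover_cuts: tuple[float, float] = (0.25, 0.66)
    hazard_method: str = "hazard"
    covariates: tuple[str, ...] = ("w_adjust",)  # fitted alongside the exposure
    #: scale on which W_i enters the model; "log" floors W_i at 1e-12 first
    w_transform: str = "linear"  # linear | log
    #: restrict case (event) years, e.g. to keep clear of data edges where
    #: risk sets are truncated; risk sets and W_g still use all births
    analysis_years: tuple[int, int] | None = None

    def manifest(self) -> dict:
        cfg = asdict(self)
        blob = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
            "heatbirth_version": __version__,
        }


@dataclass
class AnalysisResult:
    """Tables produced by :func:`run_analysis`."""

    fits: pd.DataFrame
    pooled: pd.DataFrame
    hetero: pd.DataFrame
    exclusions: pd.DataFrame
    manifest: dict


def _stratum_assignment(births: pd.DataFrame, area: pd.DataFrame | None,
                        var: str, config: AnalysisConfig) -> pd.Series:
    """Stratum level of each birth for one stratification variable."""
    if var == "none":
        return pd.Series("all", index=births.index)
    if var == "age":
        return births["age_group"]
    if var == "education":
        return births["edu_group"]
    if area is None:
        raise ValueError(f"stratification by {var!r} needs the area table")
    if var == "sdi":
        sdi = births["zcta_id"].map(
            area.set_index("zcta_id")["sdi_score"]
        ).astype(float)  # zcta_id may be categorical; compare on plain floats
        return pd.Series(
            np.where(sdi < config.sdi_cut, "low", "high"), index=births.index
        )
    if var == "landcover":
        imp = births["zcta_id"].map(
            area.set_index("zcta_id")["impervious_frac"]
        ).astype(float)
        lo, hi = config.landcover_cuts
        return pd.Series(
            np.select([imp < lo, imp <= hi], ["<25%", "25-66%"], ">66%"),
            index=births.index,
        )
    raise ValueError(f"unknown stratification variable {var!r}")


def run_analysis(
    births: pd.DataFrame,
    grid_temps: pd.DataFrame | None = None,
    grid_map: pd.DataFrame | None = None,
    area: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    zcta_series: dict | None = None,
) -> AnalysisResult:
    """Run the full stratified analysis.

    Temperature input is either the gridded tables (``grid_temps`` +
    ``grid_map``) or precomputed ZCTA series (``zcta_series``).  Births
    must carry ``birth_id, state, zcta_id, birth_date, ga_weeks`` plus
    any subgroup columns used for stratification.
    """
    config = config or AnalysisConfig()
    if zcta_series is None:
        if grid_temps is None or grid_map is None:
            raise ValueError("provide either zcta_series or grid tables")
        zcta_series = zcta_daily_series(
            grid_temps, grid_map, require_zctas=births["zcta_id"].unique()
        )
    exposures = exposure_table(
        zcta_series,
        lag_start=config.window_lag_start,
        window=config.window_length,
        percentile=config.threshold_percentile,
    )

    births = births.copy()
    births["birth_date"] = pd.to_datetime(births["birth_date"])
    fit_rows, excl_rows = [], []

    for outcome in config.outcomes:
        for state, sb in births.groupby("state", sort=True, observed=True):
            hazard = birth_week_hazard(sb, method=config.hazard_method)
            # W_i is only needed on stratum days, which all lie in the warm
            # season (month matching); compute it per warm-season window
            m0, m1 = config.warm_months
            if config.analysis_years is not None:
                years = range(config.analysis_years[0], config.analysis_years[1] + 1)
            else:
                years = sorted(sb["birth_date"].dt.year.unique())
            if config.w_transform not in ("linear", "log"):
                raise ValueError(f"unknown w_transform {config.w_transform!r}")
            adj = pd.concat(
                [
                    adjustment_table(
                        sb,
                        pd.date_range(
                            pd.Timestamp(year=y, month=m0, day=1),
                            pd.Timestamp(year=y, month=m1, day=1)
                            + pd.offsets.MonthEnd(0),
                            freq="D",
                        ),
                        outcome,
                        hazard,
                    )
                    for y in years
                ],
                ignore_index=True,
            )
            if config.boundary_policy == "exclude":
                adj.loc[adj["boundary_flag"], "w_i"] = np.nan
            for var in config.strat_vars:
                levels = _stratum_assignment(sb, area, var, config)
                if var == "education" and (levels == "missing").all():
                    log.warning(
                        "state %s lacks education data; excluded from the "
                        "education-stratified analysis", state
                    )
                    continue
                for level in STRAT_LEVELS[var]:
                    in_level = levels == level
                    if config.analysis_years is not None:
                        y0, y1 = config.analysis_years
                        in_level &= sb["birth_date"].dt.year.between(y0, y1)
                    cases = sb[in_level]
                    if cases.empty:
                        continue
                    strata, excl = assemble_strata(
                        cases, exposures, adj, outcome,
                        warm_months=config.warm_months,
                    )
                    excl_rows.append(
                        {"outcome": outcome, "state": state,
                         "stratum_var": var, "stratum_level": level, **excl}
                    )
                    for hw in config.hw_defs:
                        row = {
                            "state": state, "outcome": outcome,
                            "stratum_var": var, "stratum_level": level,
                            "hw_def": hw, "beta": np.nan, "se": np.nan,
                            "or": np.nan, "lcl": np.nan, "ucl": np.nan,
                            "n_cases": strata["is_case"].sum() if len(strata) else 0,
                            "n_informative": 0, "converged": False,
                        }
                        if len(strata):
                            col = HW_COLUMNS[hw]
                            fs = strata.copy()
                            fs[col] = fs[col].astype(float)
                            if (
                                config.w_transform == "log"
                                and "w_adjust" in fs.columns
                            ):
                                fs["w_adjust"] = np.log(
                                    fs["w_adjust"].clip(lower=1e-12)
                                )
                            try:
                                fit = fit_clogit(
                                    fs, [col, *config.covariates]
                                )
                                row.update(
                                    beta=fit.beta[0], se=fit.se[0],
                                    n_informative=fit.n_informative,
                                    converged=fit.converged,
                                )
                                if fit.converged:
                                    orr, lcl, ucl = fit.or_ci()
                                    row.update({"or": orr, "lcl": lcl, "ucl": ucl})
                                else:
                                    log.warning(
                                        "non-convergence: %s %s %s=%s %s (%s)",
                                        state, outcome, var, level, hw,
                                        fit.message,
                                    )
                            except ValueError as err:
                                log.warning(
                                    "skipping %s %s %s=%s %s: %s",
                                    state, outcome, var, level, hw, err,
                                )
                        fit_rows.append(row)

    fits = pd.DataFrame(fit_rows)
    pooled_rows, het_rows = [], []
    if len(fits):
        ok = fits[fits["converged"] & np.isfinite(fits["se"]) & (fits["se"] > 0)]
        for key, sub in ok.groupby(
            ["outcome", "stratum_var", "stratum_level", "hw_def"], sort=False
        ):
            pr = ivw_pool(sub[["beta", "se"]].to_numpy())
            orr, lcl, ucl = pr.or_ci()
            pooled_rows.append(
                dict(zip(["outcome", "stratum_var", "stratum_level", "hw_def"], key))
                | {"beta": pr.beta, "se": pr.se, "or": orr, "lcl": lcl,
                   "ucl": ucl, "k_states": pr.k,
                   "n_cases": int(sub["n_cases"].sum())}
            )
    pooled = pd.DataFrame(pooled_rows)
    if len(pooled):
        for (outcome, var, hw), sub in pooled.groupby(
            ["outcome", "stratum_var", "hw_def"], sort=False
        ):
            if var == "none" or len(sub) < 2:
                continue
            est = sub[["beta", "se"]].to_numpy()
            chi2, df, p = heterogeneity_wald(est)
            het_rows.append(
                {"outcome": outcome, "stratum_var": var, "hw_def": hw,
                 "stat_type": "wald", "stat": chi2, "df": df, "p": p}
            )
            if len(sub) == 2:
                z, pz = heterogeneity_z(est[0], est[1])
                het_rows.append(
                    {"outcome": outcome, "stratum_var": var, "hw_def": hw,
                     "stat_type": "z", "stat": z, "df": 1, "p": pz}
                )
    hetero = pd.DataFrame(het_rows)
    return AnalysisResult(
        fits=fits,
        pooled=pooled,
        hetero=hetero,
        exclusions=pd.DataFrame(excl_rows),
        manifest=config.manifest(),
    )


def summarize(results: AnalysisResult) -> tuple[pd.DataFrame, str]:
    """Tidy forest-plot table and a text report of the pooled results.

    One row per (outcome, heat-wave definition, stratum level) with OR,
    95% CI and the stratum variable's heterogeneity p-value, in
    deterministic order.
    """
    if len(results.pooled) == 0:
        log.warning("no pooled results to summarize")
        return pd.DataFrame(
            columns=["outcome", "stratum_var", "stratum_level", "hw_def",
                     "or", "lcl", "ucl", "n_cases", "p_heterogeneity"]
        ), "no results\n"
    tab = results.pooled.copy()
    het = results.hetero
    if len(het):
        wald = het[het["stat_type"] == "wald"][
            ["outcome", "stratum_var", "hw_def", "p"]
        ].rename(columns={"p": "p_heterogeneity"})
        tab = tab.merge(wald, on=["outcome", "stratum_var", "hw_def"], how="left")
    else:
        tab["p_heterogeneity"] = np.nan
    order = {lv: i for lvls in STRAT_LEVELS.values() for i, lv in enumerate(lvls)}
    tab["_lv"] = tab["stratum_level"].map(order)
    tab = tab.sort_values(
        ["outcome", "stratum_var", "hw_def", "_lv"]
    ).drop(columns="_lv").reset_index(drop=True)

    lines = []
    for (outcome, var, hw), sub in tab.groupby(
        ["outcome", "stratum_var", "hw_def"], sort=True
    ):
        p_het = sub["p_heterogeneity"].iloc[0]
        head = f"{outcome} | {var} | {hw}"
        if np.isfinite(p_het):
            head += f"  (heterogeneity p = {p_het:.3f})"
        lines.append(head)
        for _, r in sub.iterrows():
            lines.append(
                f"  {r['stratum_level']:>8}: OR {r['or']:.3f} "
                f"({r['lcl']:.3f}, {r['ucl']:.3f})  cases {int(r['n_cases'])}"
            )
    return tab[
        ["outcome", "stratum_var", "stratum_level", "hw_def", "or", "lcl",
         "ucl", "n_cases", "p_heterogeneity"]
    ], "\n".join(lines) + "\n"
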