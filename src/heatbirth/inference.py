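"""Conditional logistic regression for 1-case matched sets.

Each case-crossover stratum contributes one term to the conditional
likelihood

    l(beta) = sum_s [ x_case . beta - log sum_{j in s} exp(x_j . beta) ]

which is the likelihood of the case day given that exactly one event
occurred in the stratum.  The log-likelihood is concave; it is
maximised by Newton-Raphson with analytic gradient and observed
information, with step-halving as a safeguard.  Strata whose
covariates are constant across days carry no information and are
dropped from the likelihood (but counted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FitResult", "clogit_loglik", "fit_clogit", "wald_ci"]

GRAD_TOL = 1e-8
MAX_ITER = 50
#: |beta| (on the within-stratum-sd scale) beyond which the likelihood is
#: treated as monotone (perfect separation) rather than converging.
SEPARATION_BOUND = 15.0


@dataclass
class FitResult:
    """Maximum conditional-likelihood fit of a matched-set logistic model."""

    covariates: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_strata: int
    n_informative: int
    converged: bool
    message: str = ""

    def or_ci(self, which: int = 0, level: float = 0.95):
        """Odds ratio and CI for one coefficient (default: the exposure)."""
        return wald_ci(self.beta[which], self.se[which], level)

    def wald_p(self, which: int = 0) -> float:
        """Two-sided Wald p-value for one coefficient."""
        z = self.beta[which] / self.se[which]
        return float(2.0 * stats.norm.sf(abs(z)))


def _prepare(strata: pd.DataFrame, covariates, group_col, case_col):
    df = strata.sort_values(group_col, kind="stable")
    groups, _ = pd.factorize(df[group_col], sort=False)
    X = df[list(covariates)].to_numpy(dtype=float)
    y = df[case_col].to_numpy(dtype=bool)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate values in strata")
    starts = np.flatnonzero(np.r_[True, np.diff(groups) != 0])
    cases_per = np.add.reduceat(y.astype(int), starts)
    if np.any(cases_per != 1):
        bad = int(np.argmax(cases_per != 1))
        raise ValueError(
            f"stratum {df[group_col].iloc[starts[bad]]!r} has "
            f"{cases_per[bad]} case days; exactly one required"
        )
    return X, y, groups, starts


def _loglik_parts(X, y, groups, starts, beta):
    """Conditional log-likelihood with analytic gradient and information."""
    eta = X @ beta
    m = np.maximum.reduceat(eta, starts)
    e = np.exp(eta - m[groups])
    denom = np.add.reduceat(e, starts)
    ll = float(eta[y].sum() - (m + np.log(denom)).sum())
    p = e / denom[groups]
    grad = X[y].sum(axis=0) - p @ X
    pX = X * p[:, None]
    xbar = np.add.reduceat(pX, starts, axis=0)  # per-stratum E[x]
    info = pX.T @ X - xbar.T @ xbar
    return ll, grad, info


def clogit_loglik(
    strata: pd.DataFrame,
    beta,
    covariates,
    group_col: str = "birth_id",
    case_col: str = "is_case",
):
    """Evaluate the conditional log-likelihood, gradient and information.

    ``strata`` is a long table with one row per stratum-day (see
    :func:`heatbirth.design.assemble_strata`); exactly one case per
    stratum is required.
    """
    X, y, groups, starts = _prepare(strata, covariates, group_col, case_col)
    return _loglik_parts(X, y, groups, starts, np.asarray(beta, dtype=float))


def fit_clogit(
    strata: pd.DataFrame,
    covariates,
    group_col: str = "birth_id",
    case_col: str = "is_case",
) -> FitResult:
    """Fit the conditional logistic model by Newton-Raphson.

    The first covariate is conventionally the exposure of interest.
    Covariates are internally rescaled to unit average within-stratum
    standard deviation for numerical conditioning; estimates are
    reported on the original scale.  Monotone likelihoods (perfect
    separation) are flagged via ``converged=False`` rather than raised.

    Raises
    ------
    ValueError
        If no stratum shows within-stratum variation of the exposure
        covariate (nothing to estimate), or strata are malformed.
    """
    covariates = list(covariates)
    X, y, groups, starts = _prepare(strata, covariates, group_col, case_col)
    n_strata = len(starts)
    sizes = np.diff(np.r_[starts, len(y)])

    gmean = np.add.reduceat(X, starts, axis=0) / sizes[:, None]
    resid = X - gmean[groups]
    within_var = np.add.reduceat(resid**2, starts, axis=0)
    informative = within_var[:, 0] > 0
    n_informative = int(informative.sum())
    if n_informative == 0:
        raise ValueError(
            f"no stratum has within-stratum variation in {covariates[0]!r}; "
            "the exposure effect is not estimable"
        )
    any_var = (within_var > 0).any(axis=1)
    keep = any_var[groups]
    X, y, groups = X[keep], y[keep], groups[keep]
    groups = pd.factorize(groups)[0]
    starts = np.flatnonzero(np.r_[True, np.diff(groups) != 0])

    scale = np.sqrt(within_var.sum(axis=0) / len(keep))
    degenerate = scale == 0  # constant within every stratum: not estimable
    scale[degenerate] = 1.0
    Xs = X / scale

    beta = np.zeros(X.shape[1])
    ll, grad, info = _loglik_parts(Xs, y, groups, starts, beta)
    converged = False
    message = ""
    for _ in range(MAX_ITER):
        free = ~degenerate
        if np.max(np.abs(grad[free])) < GRAD_TOL:
            converged = True
            break
        step = np.zeros_like(beta)
        step[free] = np.linalg.solve(
            info[np.ix_(free, free)], grad[free]
        )
        # step-halving: concavity guarantees ascent along the Newton
        # direction for a small enough step
        t = 1.0
        for _ in range(40):
            new_beta = beta + t * step
            new = _loglik_parts(Xs, y, groups, starts, new_beta)
            if new[0] >= ll - 1e-12:
                break
            t /= 2.0
        improved = new[0] - ll
        beta = new_beta
        ll, grad, info = new
        # on large problems float accumulation floors the gradient above
        # the absolute tolerance; a machine-precision-stationary likelihood
        # at a near-zero gradient is the optimum (the likelihood is concave)
        if improved <= 1e-10 * (1.0 + abs(ll)) and np.max(np.abs(grad[~degenerate])) < 1e-5:
            converged = True
            break
        if np.max(np.abs(beta[~degenerate])) > SEPARATION_BOUND:
            message = "monotone likelihood (possible perfect separation)"
            break
    else:
        message = f"no convergence in {MAX_ITER} Newton iterations"

    se = np.full_like(beta, np.nan)
    if converged:
        free = ~degenerate
        cov = np.linalg.inv(info[np.ix_(free, free)])
        se[free] = np.sqrt(np.diag(cov))
        # a monotone likelihood can satisfy the gradient tolerance once the
        # exponentials saturate; a huge coefficient with a flat curvature
        # (both on the within-stratum-sd scale) marks it
        if np.any((np.abs(beta[free]) > 5.0) & (se[free] > 50.0)):
            converged = False
            message = "monotone likelihood (possible perfect separation)"
    beta_out = np.where(degenerate, np.nan, beta / scale)
    se_out = np.where(degenerate, np.nan, se / scale)
    return FitResult(
        covariates=covariates,
        beta=beta_out,
        se=se_out,
        loglik=ll,
        n_strata=n_strata,
        n_informative=n_informative,
        converged=converged,
        message=message,
    )


def wald_ci(beta: float, se: float, level: float = 0.95):
    """Odds ratio with a two-sided Wald confidence interval.

    Returns ``(or, lower, upper)`` with ``or = exp(beta)`` and bounds
    ``exp(beta -/+ z * se)`` for the normal quantile ``z`` of ``level``.
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    z = stats.norm.ppf(0.5 + level / 2.0)
    with np.errstate(over="ignore"):  # a very weak fit may have an inf bound
        return (
            float(np.exp(beta)),
            float(np.exp(beta - z * se)),
            float(np.exp(beta + z * se)),
        )
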