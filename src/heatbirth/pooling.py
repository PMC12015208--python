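"""Fixed-effect inverse-variance pooling and heterogeneity tests.

State-specific log odds ratios are combined with weights 1/se^2
(fixed-effect meta-analysis).  Differences between subgroup estimates
are tested with a two-group Z score or, for any number of groups, a
Wald-type chi-square statistic comparing each estimate with the pooled
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .inference import wald_ci

__all__ = ["PooledResult", "ivw_pool", "heterogeneity_z", "heterogeneity_wald"]


@dataclass
class PooledResult:
    """Inverse-variance-weighted summary of k independent estimates."""

    beta: float
    se: float
    k: int
    weights: np.ndarray

    def or_ci(self, level: float = 0.95):
        return wald_ci(self.beta, self.se, level)


def _check_ses(se: np.ndarray) -> None:
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all standard errors must be finite and positive")


def ivw_pool(estimates) -> PooledResult:
    """Pool (beta, se) pairs with inverse-variance weights.

    ``beta_pooled = sum(w_k beta_k) / sum(w_k)`` and
    ``se_pooled = sum(w_k)^(-1/2)`` with ``w_k = 1/se_k^2``.
    """
    est = np.asarray(list(estimates), dtype=float)
    if est.ndim != 2 or est.shape[1] != 2 or est.shape[0] < 1:
        raise ValueError("estimates must be a non-empty list of (beta, se) pairs")
    beta, se = est[:, 0], est[:, 1]
    _check_ses(se)
    w = 1.0 / se**2
    return PooledResult(
        beta=float((w * beta).sum() / w.sum()),
        se=float(w.sum() ** -0.5),
        k=len(beta),
        weights=w,
    )


def heterogeneity_z(est_a, est_b):
    """Two-sided Z test for a difference between two pooled estimates.

    ``z = (beta_a - beta_b) / sqrt(se_a^2 + se_b^2)``; returns (z, p).
    """
    (ba, sa), (bb, sb) = est_a, est_b
    _check_ses(np.array([sa, sb], dtype=float))
    z = (ba - bb) / np.hypot(sa, sb)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def heterogeneity_wald(estimates):
    """Wald chi-square test of homogeneity across k >= 2 estimates.

    ``chi2 = sum w_k (beta_k - beta_pooled)^2`` with ``w_k = 1/se_k^2``,
    referred to a chi-square with k-1 degrees of freedom.  Returns
    ``(chi2, df, p)``.  At k = 2 the statistic equals the square of
    :func:`heterogeneity_z`.
    """
    est = np.asarray(list(estimates), dtype=float)
    if est.ndim != 2 or est.shape[0] < 2:
        raise ValueError("heterogeneity test needs at least two estimates")
    beta, se = est[:, 0], est[:, 1]
    _check_ses(se)
    w = 1.0 / se**2
    pooled = (w * beta).sum() / w.sum()
    chi2 = float((w * (beta - pooled) ** 2).sum())
    df = len(beta) - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))
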