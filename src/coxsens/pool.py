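"""Rubin's rules for combining per-imputation Cox estimates.

Scalar (per-coefficient) pooling: the pooled estimate is the mean of the m
per-imputation estimates; its variance is the mean within-imputation variance
W plus (1 + 1/m) times the between-imputation sample variance B. Confidence
intervals use the normal 1.96 multiplier, matching the convention of the
analyses this package reproduces; the small-m t-based degrees of freedom are
available but not used for the default intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PooledEstimate", "rubin_combine"]


@dataclass
class PooledEstimate:
    beta_bar: np.ndarray
    within: np.ndarray
    between: np.ndarray
    total_var: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    m: int
    covariate_names: list[str] | None = None

    @property
    def df(self) -> np.ndarray:
        """Classical Rubin (1987) degrees of freedom (m-1)(1 + W/((1+1/m)B))^2.

        Infinite when B = 0. Not used by the default normal-theory intervals.
        """
        with np.errstate(divide="ignore"):
            r = (1.0 + 1.0 / self.m) * self.between / self.within
            return (self.m - 1) * (1.0 + 1.0 / r) ** 2

    def summary(self) -> pd.DataFrame:
        idx = self.covariate_names or [f"x{i}" for i in range(self.beta_bar.size)]
        return pd.DataFrame(
            {
                "estimate": self.beta_bar,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "within": self.within,
                "between": self.between,
                "m": self.m,
            },
            index=idx,
        )


def rubin_combine(
    estimates, variances, covariate_names: list[str] | None = None
) -> PooledEstimate:
    """Pool per-imputation estimates and variances by Rubin's rules.

    Parameters
    ----------
    estimates : sequence of length-p coefficient vectors (one per imputation)
    variances : sequence of length-p per-coefficient variance vectors

    Returns the pooled estimate with total variance ``W + (1 + 1/m) B``,
    where B uses the (m-1) divisor, and normal 95% intervals.
    """
    est = np.atleast_2d(np.asarray(estimates, dtype=float))
    var = np.atleast_2d(np.asarray(variances, dtype=float))
    m = est.shape[0]
    if m < 2:
        raise ValueError(f"Rubin's rules require at least 2 imputations, got {m}")
    if var.shape != est.shape:
        raise ValueError(f"estimates shape {est.shape} != variances shape {var.shape}")
    beta_bar = est.mean(axis=0)
    within = var.mean(axis=0)
    between = est.var(axis=0, ddof=1)
    total = within + (1.0 + 1.0 / m) * between
    se = np.sqrt(total)
    return PooledEstimate(
        beta_bar=beta_bar,
        within=within,
        between=between,
        total_var=total,
        se=se,
        ci_low=beta_bar - 1.96 * se,
        ci_high=beta_bar + 1.96 * se,
        m=m,
        covariate_names=covariate_names,
    )
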