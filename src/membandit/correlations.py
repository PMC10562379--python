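"""Rank-correlation machinery for the lifespan analyses.

Because model parameters and behavioural scores carry ties, associations
are measured with Kendall's tau-b (tie-corrected).  For comparing a
correlation between two independent samples, tau is first mapped to the
corresponding linear correlation, R = sin(pi * tau / 2), and the two R
values are compared by Fisher's z-test.  "Age-controlled" correlations
residualise the model-parameter variable on age by ordinary least squares
before correlating.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CorrelationResult",
    "kendall_tau_b",
    "tau_to_r",
    "compare_correlations",
    "residualized_correlation",
]


@dataclass(frozen=True)
class CorrelationResult:
    """A tau-b correlation with its sample size, p-value and sine-mapped
    linear-scale equivalent."""

    tau_b: float
    n: int
    p: float
    r_equivalent: float
    partial: bool = False


def kendall_tau_b(x, y) -> CorrelationResult:
    """Tie-corrected Kendall rank correlation with an asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for an all-tied sequence")
    res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    tau = float(res.statistic)
    if not math.isfinite(tau):
        raise ValueError("correlation undefined (degenerate input)")
    return CorrelationResult(
        tau_b=tau, n=len(x), p=float(res.pvalue), r_equivalent=tau_to_r(tau)
    )


def tau_to_r(tau: float) -> float:
    """Greiner's relation mapping tau to a linear-scale correlation."""
    if abs(tau) > 1.0:
        raise ValueError(f"|tau|={abs(tau)} exceeds 1")
    return math.sin(0.5 * math.pi * tau)


def compare_correlations(
    tau1: float, n1: int, tau2: float, n2: int
) -> tuple[float, float]:
    """Fisher z-test between two independent tau-b correlations.

    Both taus are first sine-mapped to linear R; the statistic is
    ``(atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p-value.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("each sample must have n >= 4")
    r1 = tau_to_r(tau1)
    r2 = tau_to_r(tau2)
    if abs(r1) >= 1.0 or abs(r2) >= 1.0:
        raise ValueError("Fisher transform undefined at |r| = 1")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def residualized_correlation(x, y, covariate, both: bool = False) -> CorrelationResult:
    """Kendall tau-b between OLS residuals of ``x`` on ``covariate`` and
    ``y`` (or the residuals of both, with ``both=True``).

    A constant covariate cannot be regressed out; the plain correlation
    is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    if not (len(x) == len(y) == len(cov)) or len(x) < 4:
        raise ValueError("x, y, covariate must be equal-length with n >= 4")
    if np.all(cov == cov[0]):
        warnings.warn("constant covariate; returning the plain correlation")
        res = kendall_tau_b(x, y)
        return CorrelationResult(res.tau_b, res.n, res.p, res.r_equivalent, partial=True)

    def _residuals(v: np.ndarray) -> np.ndarray:
        design = np.column_stack([np.ones_like(cov), cov])
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        return v - design @ beta

    rx = _residuals(x)
    ry = _residuals(y) if both else y
    res = kendall_tau_b(rx, ry)
    return CorrelationResult(res.tau_b, res.n, res.p, res.r_equivalent, partial=True)
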