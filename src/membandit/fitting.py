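"""Maximum a-posteriori fitting of the hybrid model.

Per participant, the five parameters are optimised on an unbounded scale
and logistic-mapped to their intervals inside the objective.  Weakly
informative priors on the bounded scale — Beta(1.1, 1.1) for the two
learning/decay rates, Normal(0, 10) truncated to [0, 20] for the inverse
temperatures and to [-3, 3] for perseveration — are added to the
learning-phase log likelihood.  The optimiser restarts from fresh random
points until the incumbent optimum has not changed (within tolerance) for
a configured number of consecutive runs.

Participants whose fitted model is not significantly better than the
fixed chance model (P(choose) = 1/3 on every trial) are flagged for
exclusion by a likelihood-ratio chi-square test with five degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit
from sklearn.base import BaseEstimator

from .data import ChoiceDataset
from .hybrid import (
    PARAM_BOUNDS,
    PARAM_NAMES,
    AgentParams,
    chance_log_likelihood,
    sequence_log_likelihood,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "HybridMAPEstimator",
    "transform_to_bounds",
    "transform_from_bounds",
    "log_prior",
    "log_posterior",
    "fit_map",
    "exclusion_test",
]

_LO = np.array([PARAM_BOUNDS[n][0] for n in PARAM_NAMES])
_HI = np.array([PARAM_BOUNDS[n][1] for n in PARAM_NAMES])

# Prior log-density constants, evaluated in closed form for speed:
# Beta(1.1, 1.1) for the rates; Normal(0, 10) truncated to [0, 20] for the
# inverse temperatures and to [-3, 3] for perseveration.
import math as _math

from scipy.special import betaln as _betaln

_BETA_A = 1.1
_LOGBETA_NORM = -float(_betaln(_BETA_A, _BETA_A))
_NORM_SCALE = 10.0
_LOG_NORM_CONST = -0.5 * _math.log(2.0 * _math.pi) - _math.log(_NORM_SCALE)
# Truncation masses: Phi(b) - Phi(a) on the standard scale.
_Z_BETA = float(stats.norm.cdf(2.0) - stats.norm.cdf(0.0))    # [0, 20]
_Z_PERSEV = float(stats.norm.cdf(0.3) - stats.norm.cdf(-0.3))  # [-3, 3]


def _beta_logpdf(x: float) -> float:
    if x <= 0.0 or x >= 1.0:
        return -_math.inf
    return _LOGBETA_NORM + (_BETA_A - 1.0) * (_math.log(x) + _math.log1p(-x))


def _truncnorm_logpdf(x: float, z_mass: float) -> float:
    return _LOG_NORM_CONST - 0.5 * (x / _NORM_SCALE) ** 2 - _math.log(z_mass)


def transform_to_bounds(unbounded: np.ndarray) -> AgentParams:
    """Scaled-logistic map from R^5 to the bounded parameter space."""
    z = np.asarray(unbounded, dtype=float)
    if z.shape != (5,):
        raise ValueError("expected a length-5 unbounded vector")
    return AgentParams.from_array(_LO + (_HI - _LO) * expit(z))


def transform_from_bounds(params: AgentParams) -> np.ndarray:
    """Inverse map; requires strictly interior parameter values."""
    p = params.as_array()
    frac = (p - _LO) / (_HI - _LO)
    if np.any(frac <= 0.0) or np.any(frac >= 1.0):
        raise ValueError("parameters on a bound have no finite preimage")
    return logit(frac)


def log_prior(params: AgentParams) -> float:
    """Joint log prior density, evaluated on the bounded scale."""
    return (
        _beta_logpdf(params.alpha_rl)
        + _beta_logpdf(params.alpha_sample)
        + _truncnorm_logpdf(params.beta_rl, _Z_BETA)
        + _truncnorm_logpdf(params.beta_sample, _Z_BETA)
        + _truncnorm_logpdf(params.beta_p, _Z_PERSEV)
    )


@dataclass(frozen=True)
class FitConfig:
    """Settings for the restart loop and the exclusion test."""

    use_priors: bool = True
    stability_count: int = 5
    max_restarts: int = 50
    stability_tol: float = 1e-6
    start_scale: float = 3.0
    exclusion_alpha: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.stability_count < 1:
            raise ValueError("stability_count must be >= 1")
        if self.stability_tol <= 0:
            raise ValueError("stability_tol must be positive")
        if self.max_restarts < self.stability_count:
            raise ValueError("max_restarts must allow the stability run")


@dataclass
class FitResult:
    """Per-participant MAP fit."""

    params: AgentParams
    unbounded: np.ndarray
    log_posterior: float
    log_likelihood: float
    n_restarts: int
    excluded: bool | None = None
    exclusion_pvalue: float | None = None


def _log_prior_vec(p: np.ndarray) -> float:
    return (
        _beta_logpdf(p[0])
        + _beta_logpdf(p[1])
        + _truncnorm_logpdf(p[2], _Z_BETA)
        + _truncnorm_logpdf(p[3], _Z_BETA)
        + _truncnorm_logpdf(p[4], _Z_PERSEV)
    )


def _learning_arrays(dataset: ChoiceDataset) -> tuple[np.ndarray, np.ndarray]:
    choices, rewards = dataset.learning_arrays()
    return (
        np.ascontiguousarray(choices, dtype=np.int64),
        np.ascontiguousarray(rewards, dtype=np.int64),
    )


def log_posterior(
    unbounded: np.ndarray, dataset: ChoiceDataset, config: FitConfig | None = None
) -> float:
    """Learning-phase log likelihood plus (optionally) the log prior."""
    config = config or FitConfig()
    params = transform_to_bounds(unbounded)
    lp = sequence_log_likelihood(dataset, params)
    if config.use_priors:
        lp += log_prior(params)
    return lp


class HybridMAPEstimator(BaseEstimator):
    """Scikit-learn-style MAP estimator for the hybrid choice model.

    Parameters mirror :class:`FitConfig`.  After :meth:`fit` the instance
    exposes ``params_`` (bounded-scale :class:`AgentParams`),
    ``unbounded_``, ``log_posterior_``, ``log_likelihood_``,
    ``n_restarts_``, ``excluded_`` and ``exclusion_pvalue_``.
    """

    def __init__(
        self,
        use_priors: bool = True,
        stability_count: int = 5,
        max_restarts: int = 50,
        stability_tol: float = 1e-6,
        start_scale: float = 3.0,
        exclusion_alpha: float = 0.05,
        run_exclusion_test: bool = True,
        random_state: int = 0,
    ) -> None:
        self.use_priors = use_priors
        self.stability_count = stability_count
        self.max_restarts = max_restarts
        self.stability_tol = stability_tol
        self.start_scale = start_scale
        self.exclusion_alpha = exclusion_alpha
        self.run_exclusion_test = run_exclusion_test
        self.random_state = random_state

    def _config(self) -> FitConfig:
        cfg = FitConfig(
            use_priors=self.use_priors,
            stability_count=self.stability_count,
            max_restarts=self.max_restarts,
            stability_tol=self.stability_tol,
            start_scale=self.start_scale,
            exclusion_alpha=self.exclusion_alpha,
            seed=self.random_state,
        )
        cfg.validate()
        return cfg

    def fit(self, dataset: ChoiceDataset, y=None) -> "HybridMAPEstimator":
        cfg = self._config()
        choices, rewards = _learning_arrays(dataset)
        if int((choices >= 0).sum()) < 1:
            raise ValueError("dataset has no valid learning-phase choices")
        from .hybrid import _loglik_core

        def objective(z: np.ndarray) -> float:
            # clamp off the exact bounds so the prior stays finite
            frac = np.clip(expit(z), 1e-12, 1.0 - 1e-12)
            p = _LO + (_HI - _LO) * frac
            lp = _loglik_core(choices, rewards, p[0], p[1], p[2], p[3], p[4])
            if cfg.use_priors:
                lp += _log_prior_vec(p)
            return -lp

        rng = np.random.default_rng(cfg.seed)
        best_fun = np.inf
        best_z: np.ndarray | None = None
        stable = 0
        n_runs = 0
        n_failures = 0
        while n_runs < cfg.max_restarts and stable < cfg.stability_count:
            z0 = rng.uniform(-cfg.start_scale, cfg.start_scale, size=5)
            n_runs += 1
            try:
                res = optimize.minimize(objective, z0, method="BFGS")
                fun = float(res.fun)
                if not np.isfinite(fun):
                    raise RuntimeError("non-finite objective")
            except Exception:
                n_failures += 1
                continue
            if fun < best_fun - cfg.stability_tol:
                best_fun = fun
                best_z = np.asarray(res.x)
                stable = 0
            else:
                stable += 1

        if best_z is None:
            raise RuntimeError(f"all {n_failures} optimizer restarts failed")

        self.params_ = transform_to_bounds(best_z)
        self.unbounded_ = best_z
        self.log_posterior_ = -best_fun
        self.log_likelihood_ = sequence_log_likelihood(dataset, self.params_)
        self.n_restarts_ = n_runs
        if self.run_exclusion_test:
            excluded, pval = exclusion_test(self._result(), dataset, alpha=cfg.exclusion_alpha)
            self.excluded_ = excluded
            self.exclusion_pvalue_ = pval
        else:
            self.excluded_ = None
            self.exclusion_pvalue_ = None
        return self

    def _result(self) -> FitResult:
        return FitResult(
            params=self.params_,
            unbounded=self.unbounded_,
            log_posterior=self.log_posterior_,
            log_likelihood=self.log_likelihood_,
            n_restarts=self.n_restarts_,
            excluded=getattr(self, "excluded_", None),
            exclusion_pvalue=getattr(self, "exclusion_pvalue_", None),
        )

    def result(self) -> FitResult:
        if not hasattr(self, "params_"):
            raise RuntimeError("estimator is not fitted")
        return self._result()


def fit_map(dataset: ChoiceDataset, config: FitConfig | None = None) -> FitResult:
    """MAP-fit one dataset (functional wrapper over the estimator)."""
    cfg = config or FitConfig()
    est = HybridMAPEstimator(
        use_priors=cfg.use_priors,
        stability_count=cfg.stability_count,
        max_restarts=cfg.max_restarts,
        stability_tol=cfg.stability_tol,
        start_scale=cfg.start_scale,
        exclusion_alpha=cfg.exclusion_alpha,
        random_state=cfg.seed,
    ).fit(dataset)
    return est.result()


def exclusion_test(
    fit: FitResult, dataset: ChoiceDataset, alpha: float = 0.05
) -> tuple[bool, float]:
    """Likelihood-ratio test of the fitted model against fixed chance.

    The maximised *likelihood* (not posterior) is compared with
    ``n * ln(1/3)`` by a chi-square test with five degrees of freedom; the
    participant is flagged for exclusion when the fit is not significantly
    better.  The likelihood is re-maximised starting from the MAP solution
    so the prior's pull does not penalise the comparison.
    """
    from .hybrid import _loglik_core

    choices, rewards = _learning_arrays(dataset)
    n = int((choices >= 0).sum())
    ll_chance = chance_log_likelihood(n)

    def neg_ll(z: np.ndarray) -> float:
        p = _LO + (_HI - _LO) * expit(z)
        return -_loglik_core(choices, rewards, p[0], p[1], p[2], p[3], p[4])

    res = optimize.minimize(neg_ll, fit.unbounded, method="BFGS")
    ll_ml = max(-float(res.fun), fit.log_likelihood)
    lr = max(0.0, 2.0 * (ll_ml - ll_chance))
    pval = float(stats.chi2.sf(lr, df=5))
    return pval > alpha, pval
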