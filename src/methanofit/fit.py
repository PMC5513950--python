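"""Maximum-likelihood estimation of the Gompertz parameters.

The observation model is additive iid Gaussian noise on methane, pooled over
a condition's duplicate vials (one parameter set per condition):

    m_i = M(t_i; P, Rm, lambda) + eps_i,   eps_i ~ N(0, sigma^2)

The estimate is obtained in log-parameter space by a two-stage hybrid:

1. a population-based evolutionary global search (differential evolution,
   population 200, at most 1000 generations) of the sigma-profiled negative
   log-likelihood over the prior box, with early stopping once the best
   objective improves by less than 1e-8 for 50 consecutive generations;
2. gradient-based bounded least-squares refinement (trust-region
   reflective) of the residuals over the kinetic log-parameters, started at
   the stage-1 optimum; the noise scale is then the exact joint-MLE value
   (the residual RMS, clipped to its prior bounds).

The refinement never worsens the objective: if the local stage fails or
returns a worse value, the stage-1 result is kept and ``converged`` is set
to False.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import optimize

from .dataio import AssayTimeSeries
from .errors import DegenerateDataError, ValidationError
from .model import GompertzParams, from_log, gompertz_curve, gompertz_curve_batch
from .priors import PriorFactors, PriorSpec

__all__ = ["OptimizerConfig", "MLEResult", "log_likelihood", "fit_mle"]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class OptimizerConfig:
    """Hybrid-search settings.

    population and max_generations control the evolutionary stage;
    local_tolerance is the objective tolerance of the quasi-Newton stage.
    Early stopping: the global stage halts when its best objective has not
    improved by more than ``stall_tolerance`` for ``stall_generations``
    consecutive generations.
    """

    population: int = 200
    max_generations: int = 1000
    local_tolerance: float = 1e-10
    stall_tolerance: float = 1e-8
    stall_generations: int = 50
    mutation: tuple[float, float] = (0.5, 1.0)
    recombination: float = 0.7


@dataclass(frozen=True)
class MLEResult:
    """Hybrid maximum-likelihood fit of one condition."""

    params: GompertzParams
    sigma_hat: float
    log_likelihood: float
    converged: bool
    objective_trace: tuple[float, ...]
    prior: PriorSpec
    n_obs: int

    @property
    def log_vector(self) -> np.ndarray:
        """Full log-space coordinate (ln P, ln Rm, ln lambda, ln sigma)."""
        return np.log(
            [self.params.P, self.params.Rm, self.params.lam, self.sigma_hat]
        )


def log_likelihood(
    series: AssayTimeSeries, params: GompertzParams, sigma: float
) -> float:
    """Gaussian log-likelihood of ``params`` given the pooled observations.

    Sum over every observation of all replicates of
    ``-0.5*ln(2*pi*sigma^2) - (m_i - M(t_i))^2 / (2*sigma^2)``.
    """
    if series.n_obs == 0:
        raise ValidationError("cannot evaluate the likelihood of an empty series")
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValidationError(f"sigma must be finite and > 0, got {sigma!r}")
    resid = series.methane - gompertz_curve(series.times, params)
    n = series.n_obs
    return float(
        -0.5 * n * (_LOG_2PI + 2.0 * math.log(sigma))
        - float(resid @ resid) / (2.0 * sigma * sigma)
    )


def _profiled_nll_factory(t: np.ndarray, m: np.ndarray, sigma_lo: float, sigma_hi: float):
    """Vectorised sigma-profiled negative log-likelihood over log-parameters.

    For each kinetic log-vector the noise scale is profiled out analytically
    (its MLE is the residual RMS) and clipped to the prior's sigma bounds.
    Accepts an (3, S) array (differential_evolution's vectorised calling
    convention) and returns length-S values.
    """
    n = t.size

    def nll(x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(x.T if x.ndim == 2 else x)  # (S, 3)
        pred = gompertz_curve_batch(t, np.exp(x[:, 0]), np.exp(x[:, 1]), np.exp(x[:, 2]))
        ssr = np.sum((m[None, :] - pred) ** 2, axis=1)
        sigma = np.clip(np.sqrt(ssr / n), sigma_lo, sigma_hi)
        out = 0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma)) + ssr / (2.0 * sigma**2)
        return out if out.size > 1 else float(out[0])

    return nll


def _full_nll_factory(t: np.ndarray, m: np.ndarray):
    """Negative log-likelihood over the full 4-vector (kinetics + ln sigma)."""
    n = t.size

    def nll(v: np.ndarray) -> float:
        pred = gompertz_curve_batch(t, *np.exp(v[:3, None]))[0]
        ssr = float(np.sum((m - pred) ** 2))
        log_sigma = v[3]
        return 0.5 * n * (_LOG_2PI + 2.0 * log_sigma) + ssr / (
            2.0 * math.exp(2.0 * log_sigma)
        )

    return nll


def _check_not_degenerate(series: AssayTimeSeries) -> None:
    m = series.methane
    if np.allclose(m, m[0]):
        raise DegenerateDataError(
            f"condition {series.condition_id!r}: methane series is constant "
            "(no kinetics to fit)"
        )


def fit_mle(
    series: AssayTimeSeries,
    config: OptimizerConfig = OptimizerConfig(),
    seed: Optional[int] = None,
    prior: Optional[PriorSpec] = None,
    prior_factors: PriorFactors = PriorFactors(),
) -> MLEResult:
    """Hybrid global+local maximum-likelihood fit in log-parameter space.

    Deterministic for a given (series, config, seed).  The returned
    log-likelihood is never below the global stage's optimum.
    """
    if seed is None:
        raise ValidationError("fit_mle requires an explicit seed")
    _check_not_degenerate(series)
    if prior is None:
        prior = PriorSpec.from_series(series, prior_factors)
    t, m = series.times, series.methane
    sigma_lo, sigma_hi = prior.sigma_bounds
    profiled = _profiled_nll_factory(t, m, sigma_lo, sigma_hi)

    rng = np.random.default_rng(seed)
    lo, hi = prior.kinetic_lower, prior.kinetic_upper
    init = lo + (hi - lo) * rng.random((config.population, 3))

    trace: list[float] = []

    def _early_stop(intermediate_result) -> bool:
        trace.append(float(intermediate_result.fun))
        k = config.stall_generations
        if len(trace) > k and trace[-k - 1] - trace[-1] < config.stall_tolerance:
            return True
        return False

    de = optimize.differential_evolution(
        profiled,
        bounds=list(zip(lo, hi)),
        init=init,
        maxiter=config.max_generations,
        mutation=config.mutation,
        recombination=config.recombination,
        tol=0.0,
        seed=int(rng.integers(2**31 - 1)),
        polish=False,
        vectorized=True,
        updating="deferred",
        callback=_early_stop,
    )
    x_global = np.asarray(de.x, dtype=float)

    def residuals(x: np.ndarray) -> np.ndarray:
        return m - gompertz_curve_batch(t, *np.exp(x[:, None]))[0]

    def joint_vector(x: np.ndarray) -> np.ndarray:
        """Append the exact joint-MLE noise scale (clipped residual RMS)."""
        r = residuals(x)
        sigma = float(np.clip(np.sqrt(np.mean(r * r)), sigma_lo, sigma_hi))
        return np.append(x, math.log(sigma))

    full = _full_nll_factory(t, m)
    v_best = joint_vector(x_global)
    nll_best = full(v_best)
    converged = False
    try:
        local = optimize.least_squares(
            residuals,
            x_global,
            bounds=(lo, hi),
            method="trf",
            xtol=config.local_tolerance,
            ftol=config.local_tolerance,
            gtol=config.local_tolerance,
        )
        v_local = joint_vector(np.asarray(local.x, dtype=float))
        nll_local = full(v_local)
        if np.isfinite(nll_local) and nll_local <= nll_best:
            v_best, nll_best = v_local, nll_local
            converged = local.status > 0
    except (ValueError, FloatingPointError):
        converged = False

    params = from_log(v_best[:3])
    return MLEResult(
        params=params,
        sigma_hat=float(math.exp(v_best[3])),
        log_likelihood=-nll_best,
        converged=converged,
        objective_trace=tuple(trace),
        prior=prior,
        n_obs=series.n_obs,
    )
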