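"""Posterior sampling of the log-parameter vector by random-walk Metropolis.

The posterior is proportional to the Gaussian likelihood times a log-uniform
prior: constant density on a box in log space, zero outside.  Sampling
happens in the 4-dimensional log space (ln P, ln Rm, ln lambda, ln sigma);
the noise scale is sampled alongside the kinetic triple so that noise
uncertainty propagates into downstream curve bands, and its marginal is
simply ignored by stages that only need (P, Rm, lambda).

The sampler is adaptive Metropolis: a joint multivariate Gaussian proposal,
initialised from the Laplace approximation at the MLE (inverse Hessian of
the negative log-posterior, by finite differences) and adapted during
burn-in only (towards an acceptance rate of ~0.3), then frozen afterwards,
preserving the Markov property of the retained draws.  Chains start from
the MLE plus a small over-dispersed jitter, capped per coordinate at the
Laplace posterior scale so that even razor-thin posteriors (near-noiseless
data) start in a region of appreciable density.  Burn-in draws are
discarded, then every ``thinning``-th draw is retained, so each chain
contributes exactly ``(iterations - burn_in) / thinning`` rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dataio import AssayTimeSeries
from .errors import ConfigurationError, DegenerateProposalError
from .fit import MLEResult, _full_nll_factory
from .priors import PARAM_NAMES, PriorSpec

__all__ = [
    "MCMCConfig",
    "REDUCED_MCMC",
    "PosteriorDraws",
    "run_mcmc",
    "convergence_diagnostics",
]

_TARGET_ACCEPTANCE = 0.3
_RHAT_FLAG = 1.05
_ACCEPT_LOW, _ACCEPT_HIGH = 0.01, 0.90


@dataclass(frozen=True)
class MCMCConfig:
    """Chain bookkeeping and proposal settings.

    Defaults follow the full analysis protocol: three chains of 2e4
    iterations, 2e3 burn-in, thinning 10 (1800 retained per chain).
    ``initial_step`` is the starting proposal standard deviation per log
    coordinate, used only until adaptation takes over; ``jitter`` is the
    standard deviation of the over-dispersed chain initialisation around
    the MLE.
    """

    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 2_000
    thinning: int = 10
    initial_step: float = 0.1
    jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ConfigurationError("chains must be >= 1")
        if not (0 <= self.burn_in < self.iterations):
            raise ConfigurationError("burn_in must satisfy 0 <= burn_in < iterations")
        if self.thinning < 1:
            raise ConfigurationError("thinning must be >= 1")
        if self.initial_step <= 0:
            raise DegenerateProposalError(
                f"proposal scale must be > 0, got {self.initial_step!r}"
            )
        if self.jitter < 0:
            raise ConfigurationError("jitter must be >= 0")

    @property
    def retained_per_chain(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


#: Desk-scale configuration used by the calibration experiments.
REDUCED_MCMC = MCMCConfig(chains=1, iterations=5_000, burn_in=500, thinning=5)


@dataclass
class PosteriorDraws:
    """Retained draws on the natural scale with chain provenance.

    ``samples`` has shape (n_retained_total, 4), columns (P, Rm, lambda,
    sigma); ``chain_id`` and ``iteration`` tag each row with its origin.
    """

    samples: np.ndarray
    chain_id: np.ndarray
    iteration: np.ndarray
    acceptance_rates: tuple[float, ...]
    prior: PriorSpec
    warnings: tuple[str, ...] = ()

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    @property
    def n_chains(self) -> int:
        return len(self.acceptance_rates)

    def parameter(self, name: str) -> np.ndarray:
        """Pooled marginal draws of one parameter by name."""
        return self.samples[:, PARAM_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chain": self.chain_id,
                "iteration": self.iteration,
                "P": self.samples[:, 0],
                "Rm": self.samples[:, 1],
                "lambda": self.samples[:, 2],
                "sigma": self.samples[:, 3],
            }
        )

    def by_chain(self) -> list[np.ndarray]:
        return [
            self.samples[self.chain_id == c]
            for c in sorted(np.unique(self.chain_id))
        ]


def _laplace_covariance(nll, center: np.ndarray) -> Optional[np.ndarray]:
    """Inverse finite-difference Hessian of ``nll`` at ``center``, if usable."""
    d = center.size
    h = 1e-4 * np.maximum(1.0, np.abs(center))
    hess = np.empty((d, d))
    f0 = nll(center)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d)
            ej = np.zeros(d)
            ei[i] = h[i]
            ej[j] = h[j]
            if i == j:
                val = (nll(center + ei) - 2.0 * f0 + nll(center - ei)) / h[i] ** 2
            else:
                val = (
                    nll(center + ei + ej)
                    - nll(center + ei - ej)
                    - nll(center - ei + ej)
                    + nll(center - ei - ej)
                ) / (4.0 * h[i] * h[j])
            hess[i, j] = hess[j, i] = val
    if not np.all(np.isfinite(hess)):
        return None
    try:
        eigval, eigvec = np.linalg.eigh(hess)
    except np.linalg.LinAlgError:
        return None
    if np.max(eigval) <= 0:
        return None
    eigval = np.maximum(eigval, 1e-8 * np.max(eigval))
    return (eigvec / eigval) @ eigvec.T


def _run_chain(
    log_post,
    start: np.ndarray,
    config: MCMCConfig,
    rng: np.random.Generator,
    init_cov: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One adaptive Metropolis chain; returns (draws, iterations, acc_rate)."""
    d = start.size
    cov_scale = 2.38**2 / d
    chol = config.initial_step * np.eye(d)
    if init_cov is not None:
        try:
            chol = np.linalg.cholesky(cov_scale * init_cov)
        except np.linalg.LinAlgError:
            pass
    log_step = 0.0

    current = start.copy()
    current_lp = log_post(current)

    history = np.empty((config.burn_in, d))
    kept = np.empty((config.retained_per_chain, d))
    kept_iter = np.empty(config.retained_per_chain, dtype=int)
    n_kept = 0
    accepted_post = 0

    for i in range(config.iterations):
        z = rng.standard_normal(d)
        proposal = current + math.exp(log_step) * (chol @ z)
        prop_lp = log_post(proposal)
        log_alpha = prop_lp - current_lp
        accept = log_alpha >= 0 or math.log(rng.random()) < log_alpha
        if accept:
            current, current_lp = proposal, prop_lp

        if i < config.burn_in:
            history[i] = current
            # Robbins-Monro on the global step towards the target rate
            gamma = (i + 1) ** -0.6
            alpha = min(1.0, math.exp(min(log_alpha, 0.0)))
            log_step += gamma * (alpha - _TARGET_ACCEPTANCE)
            # refresh the proposal shape periodically from the burn-in history
            if i >= 99 and (i + 1) % 100 == 0:
                emp = np.cov(history[: i + 1].T) + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(cov_scale * emp)
                    log_step = 0.0
                except np.linalg.LinAlgError:
                    pass
        else:
            if accept:
                accepted_post += 1
            j = i - config.burn_in + 1
            if j % config.thinning == 0 and n_kept < kept.shape[0]:
                kept[n_kept] = current
                kept_iter[n_kept] = i + 1
                n_kept += 1

    post_iters = config.iterations - config.burn_in
    acc_rate = accepted_post / post_iters if post_iters else float("nan")
    return kept[:n_kept], kept_iter[:n_kept], acc_rate


def run_mcmc(
    series: AssayTimeSeries,
    mle: MLEResult,
    prior: Optional[PriorSpec] = None,
    config: MCMCConfig = MCMCConfig(),
    seed: Optional[int] = None,
) -> PosteriorDraws:
    """Sample the posterior of (P, Rm, lambda, sigma) for one condition.

    Deterministic given (series, mle, prior, config, seed).  Raises
    :class:`ConfigurationError` when the MLE lies outside the prior box.
    """
    if seed is None:
        raise ConfigurationError("run_mcmc requires an explicit seed")
    if prior is None:
        prior = mle.prior
    center = mle.log_vector
    if not prior.contains(center):
        raise ConfigurationError(
            "MLE log-vector lies outside the prior box; widen the prior factors"
        )

    nll = _full_nll_factory(series.times, series.methane)
    lower, upper = prior.lower, prior.upper

    def log_post(v: np.ndarray) -> float:
        if np.any(v < lower) or np.any(v > upper):
            return -math.inf
        return -nll(v)

    ss = np.random.SeedSequence(seed)
    chain_rngs = [np.random.default_rng(s) for s in ss.spawn(config.chains)]

    laplace = _laplace_covariance(nll, center)
    # over-dispersion capped at the local posterior scale, so that chains
    # starting from very peaked posteriors remain in appreciable density
    jitter_scale = np.full(center.size, config.jitter)
    if laplace is not None:
        jitter_scale = np.minimum(jitter_scale, 3.0 * np.sqrt(np.diag(laplace)))

    all_draws, all_chain, all_iter, acc_rates = [], [], [], []
    for c, rng in enumerate(chain_rngs):
        start = center + jitter_scale * rng.standard_normal(center.size)
        start = np.clip(start, lower + 1e-9, upper - 1e-9)
        draws, iters, acc = _run_chain(log_post, start, config, rng, laplace)
        all_draws.append(np.exp(draws))
        all_chain.append(np.full(draws.shape[0], c, dtype=int))
        all_iter.append(iters)
        acc_rates.append(acc)

    warnings = []
    for c, acc in enumerate(acc_rates):
        if acc < _ACCEPT_LOW or acc > _ACCEPT_HIGH:
            warnings.append(
                f"chain {c}: post-burn-in acceptance rate {acc:.3f} outside "
                f"[{_ACCEPT_LOW}, {_ACCEPT_HIGH}]; proposal tuning suspect"
            )

    draws = PosteriorDraws(
        samples=np.concatenate(all_draws),
        chain_id=np.concatenate(all_chain),
        iteration=np.concatenate(all_iter),
        acceptance_rates=tuple(acc_rates),
        prior=prior,
        warnings=tuple(warnings),
    )
    if config.chains >= 2:
        rhat = convergence_diagnostics(draws)
        bad = {k: v for k, v in rhat.items() if v > _RHAT_FLAG}
        if bad:
            draws.warnings = draws.warnings + (
                f"potential scale reduction above {_RHAT_FLAG}: {bad}",
            )
    return draws


def convergence_diagnostics(draws: PosteriorDraws) -> dict[str, float]:
    """Potential scale reduction factor per parameter (natural-scale draws).

    Computed as sqrt(1 + B_mean / W) where ``B_mean`` is the variance of the
    per-chain means and ``W`` the mean within-chain variance, so identical
    chains give exactly 1 and well-mixed independent chains values just
    above 1.  Requires at least two chains.
    """
    chains = draws.by_chain()
    if len(chains) < 2:
        raise ConfigurationError(
            "convergence diagnostics require at least 2 chains"
        )
    out = {}
    for j, name in enumerate(PARAM_NAMES):
        cols = [c[:, j] for c in chains]
        means = np.array([np.mean(c) for c in cols])
        within = float(np.mean([np.var(c, ddof=1) for c in cols]))
        between_means = float(np.var(means, ddof=1))
        if within == 0.0:
            out[name] = 1.0 if between_means == 0.0 else math.inf
        else:
            out[name] = math.sqrt(1.0 + between_means / within)
    return out
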