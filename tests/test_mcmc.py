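"""Sampler bookkeeping, prior support and convergence diagnostics."""

import numpy as np
import pytest

import methanofit as mf
from methanofit.errors import ConfigurationError, DegenerateProposalError

from conftest import make_draws


def test_retained_draw_counts(reduced_draws):
    """(iterations - burn_in)/thinning rows per chain: 4500/5 = 900."""
    assert reduced_draws.n_draws == 900
    assert mf.REDUCED_MCMC.retained_per_chain == 900
    assert mf.MCMCConfig().retained_per_chain == 1800


def test_all_draws_inside_prior_support(reduced_draws):
    logs = np.log(reduced_draws.samples)
    assert np.all(logs >= reduced_draws.prior.lower)
    assert np.all(logs <= reduced_draws.prior.upper)


def test_seed_determinism(noisy_series, noisy_mle):
    a = mf.run_mcmc(noisy_series, noisy_mle, config=mf.REDUCED_MCMC, seed=2)
    b = mf.run_mcmc(noisy_series, noisy_mle, config=mf.REDUCED_MCMC, seed=2)
    np.testing.assert_array_equal(a.samples, b.samples)
    assert a.acceptance_rates == b.acceptance_rates


def test_mle_outside_prior_box_rejected(noisy_series, noisy_mle):
    narrow = mf.PriorSpec(
        lower=noisy_mle.log_vector + 1.0, upper=noisy_mle.log_vector + 2.0
    )
    with pytest.raises(ConfigurationError):
        mf.run_mcmc(noisy_series, noisy_mle, prior=narrow,
                    config=mf.REDUCED_MCMC, seed=3)


def test_zero_proposal_scale_rejected():
    with pytest.raises(DegenerateProposalError):
        mf.MCMCConfig(initial_step=0.0)


def test_invalid_chain_settings_rejected():
    with pytest.raises(ConfigurationError):
        mf.MCMCConfig(burn_in=20_000)  # burn_in must be < iterations
    with pytest.raises(ConfigurationError):
        mf.MCMCConfig(thinning=0)


def test_posterior_median_near_truth():
    """Known truth (P=15, Rm=1.2, lambda=10), sigma=0.3, n=18 points."""
    truth = mf.GompertzParams(15, 1.2, 10)
    scenario = mf.SyntheticScenario(
        truths={"C": truth}, sigma=0.3,
        schedule=tuple(np.linspace(2, 150, 18).round(1)),
    )
    series = next(iter(mf.simulate_dataset(scenario, seed=21).values()))
    mle = mf.fit_mle(series, seed=22)
    draws = mf.run_mcmc(series, mle, seed=23)  # full 3-chain config
    assert np.median(draws.parameter("P")) == pytest.approx(15.0, rel=0.05)
    rhat = mf.convergence_diagnostics(draws)
    assert all(v < 1.05 for v in rhat.values())


def test_diagnostic_identical_chains_is_exactly_one():
    block = np.abs(np.random.default_rng(0).normal(10, 1, size=(50, 4))) + 1
    draws = make_draws(np.vstack([block, block, block]))
    draws.chain_id = np.repeat([0, 1, 2], 50)
    rhat = mf.convergence_diagnostics(draws)
    assert all(v == 1.0 for v in rhat.values())


def test_diagnostic_flags_disjoint_modes():
    rng = np.random.default_rng(1)
    a = np.abs(rng.normal(5, 0.1, size=(100, 4))) + 1
    b = np.abs(rng.normal(50, 0.1, size=(100, 4))) + 1
    draws = make_draws(np.vstack([a, b]))
    draws.chain_id = np.repeat([0, 1], 100)
    rhat = mf.convergence_diagnostics(draws)
    assert all(v > 10 for v in rhat.values())


def test_diagnostic_null_behaviour_iid_chains():
    """Three iid chains of 1800 draws sit in [0.99, 1.02]."""
    rng = np.random.default_rng(7)
    samples = np.exp(rng.standard_normal((5400, 4)) * 0.1)
    draws = make_draws(samples)
    draws.chain_id = np.repeat([0, 1, 2], 1800)
    rhat = mf.convergence_diagnostics(draws)
    assert all(0.99 <= v <= 1.02 for v in rhat.values())


def test_diagnostic_requires_two_chains(reduced_draws):
    with pytest.raises(ConfigurationError):
        mf.convergence_diagnostics(reduced_draws)


def test_diagnostic_agrees_with_arviz(noisy_series, noisy_mle):
    """Cross-check the scale-reduction statistic against arviz's rank-R-hat."""
    az = pytest.importorskip("arviz")
    draws = mf.run_mcmc(noisy_series, noisy_mle, seed=9)
    mine = mf.convergence_diagnostics(draws)
    for j, name in enumerate(("P", "Rm", "lambda", "sigma")):
        per_chain = np.stack([c[:, j] for c in draws.by_chain()])
        ref = float(az.rhat(per_chain))
        assert mine[name] == pytest.approx(ref, abs=0.02)
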