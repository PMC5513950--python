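import numpy as np
import pytest

import methanofit as mf


@pytest.fixture(scope="session")
def noisy_series():
    """One seeded default-scenario dataset (2 vials x 12 times, sigma=0.6)."""
    return next(iter(mf.simulate_dataset(mf.default_scenario(), seed=42).values()))


@pytest.fixture(scope="session")
def noisy_mle(noisy_series):
    return mf.fit_mle(noisy_series, seed=1)


@pytest.fixture(scope="session")
def reduced_draws(noisy_series, noisy_mle):
    """Reduced-config posterior (1 chain, 900 retained draws)."""
    return mf.run_mcmc(noisy_series, noisy_mle, config=mf.REDUCED_MCMC, seed=2)


def make_draws(samples: np.ndarray) -> mf.PosteriorDraws:
    """Wrap an (n, 4) natural-scale sample matrix as PosteriorDraws."""
    samples = np.asarray(samples, dtype=float)
    logs = np.log(samples)
    prior = mf.PriorSpec(lower=logs.min(axis=0) - 1.0, upper=logs.max(axis=0) + 1.0)
    return mf.PosteriorDraws(
        samples=samples,
        chain_id=np.zeros(samples.shape[0], dtype=int),
        iteration=np.arange(samples.shape[0]),
        acceptance_rates=(0.3,),
        prior=prior,
    )
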