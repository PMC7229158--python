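import numpy as np
import pytest

from burstfit.mcmc import MCMCSettings, run_mcmc


@pytest.fixture(scope="session")
def prior_chain():
    """Long no-data chain: the sampler targeting the prior alone.

    Thinning is deliberately heavy (5000) so the ~4000 retained samples
    are nearly independent; the 5%-of-current random-walk proposal has an
    integrated autocorrelation time of order 10^3 iterations on the unit
    interval.
    """
    settings = MCMCSettings(
        n_samples=20_100_000, burn_in=100_000, thin=5000, seed=20240
    )
    return run_mcmc(None, settings)


@pytest.fixture(scope="session")
def recovery_setup():
    """Synthetic counts from known parameters plus a scaled-down chain."""
    from burstfit.simulate import sample_zinb
    from burstfit.zinb import ZINBParams

    true = ZINBParams(omega=0.3, r=2.0, p=0.9)
    data = sample_zinb(true, 2000, seed=11, condition="recovery")
    settings = MCMCSettings(n_samples=50_000, burn_in=10_000, thin=10, seed=12)
    chain = run_mcmc(data.counts(), settings)
    return true, data, chain
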