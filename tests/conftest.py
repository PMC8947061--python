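"""Shared fixtures: the standard synthetic datasets and fitted posteriors.

The heavyweight objects (the one-second ~90-event scenario, its variational
fit, the Gibbs chain, and the two-dimensional fit) are session-scoped so the
whole suite pays for each of them once.
"""

import numpy as np
import pytest

from nhgps.kernels import KernelParams, SelfEffectParams
from nhgps.simulate import standard_fixture, two_dim_fixture
from nhgps.vi import MultivariateVIConfig, VIConfig, fit_vi, fit_vi_multivariate


@pytest.fixture(scope="session")
def fixture_data():
    """(truth, events): GP ground truth with 90 events in a one-second window."""
    return standard_fixture()


@pytest.fixture(scope="session")
def vi_state(fixture_data):
    truth, seq = fixture_data
    return fit_vi(seq, VIConfig(params=truth.params))


@pytest.fixture(scope="session")
def vi_state_tuned(fixture_data):
    """Variational fit with hyperparameter tuning on, as the full procedure
    prescribes (one ELBO gradient step per iteration)."""
    truth, seq = fixture_data
    return fit_vi(
        seq,
        VIConfig(params=truth.params, tune_hyperparams=True, max_iter=30,
                 learning_rate=3e-2),
    )


@pytest.fixture(scope="session")
def gibbs_chain(fixture_data):
    from nhgps.gibbs import GibbsConfig, run_gibbs

    truth, seq = fixture_data
    return run_gibbs(
        seq,
        GibbsConfig(params=truth.params, n_sweeps=5000, burn_in=1000, thin=20),
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def two_dim_data():
    return two_dim_fixture()


@pytest.fixture(scope="session")
def mv_states(two_dim_data):
    truth, seq = two_dim_data
    eff = SelfEffectParams(1.0, 0.2, 10.0)
    config = MultivariateVIConfig(
        window_end=truth.window_end,
        s_params=[(1.0, 0.3), (1.0, 0.3)],
        effects=[[eff, eff], [eff, eff]],
        n_inducing=75,
        n_quad=150,
        tol=1e-5,
    )
    return fit_vi_multivariate(seq, config)


@pytest.fixture
def toy_params():
    return KernelParams(1.0, 0.3, 1.0, 0.2, 10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
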