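import numpy as np
import pytest

import statedyn as sd


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort shared by tests that only read it."""
    cfg = sd.test_scenario(n_subjects=60, samples_per_subject=200, seed=11)
    dataset, behavior, truth = sd.simulate_cohort(cfg)
    return cfg, dataset, behavior, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_hmm_instance(rng, K, P, T):
    """A random fully-specified Gaussian HMM plus one observation sequence."""
    A = rng.dirichlet(np.ones(K) * 2.0, size=K)
    pi = rng.dirichlet(np.ones(K))
    means = rng.normal(0.0, 2.0, size=(K, P))
    covs = np.empty((K, P, P))
    for k in range(K):
        M = rng.normal(size=(P, P))
        covs[k] = M @ M.T + P * np.eye(P)
    model = sd.HMMModel(
        K=K, means=means, covariances=covs, transitions=A, initial=pi
    )
    x = rng.normal(0.0, 2.0, size=(T, P))
    return model, x
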