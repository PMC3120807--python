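import numpy as np
import pytest
from hypothesis import settings

import matchedme as mm

settings.register_profile("deterministic", deadline=None, derandomize=True)
settings.load_profile("deterministic")


def make_pair_study(seed=42, v_w=0.5, v_b=0.4, sigma2=0.3, mu=0.0, beta=1.0, n_sets=5):
    """Small P=1 study of size-2 sets drawn from the model's own mechanism.

    Returns (study, ground-truth dict).  Used by the quadrature-oracle checks,
    so the generation is written out long-hand here rather than calling the
    package's generator.
    """
    rng = np.random.default_rng(seed)
    M = mu + np.sqrt(v_b) * rng.standard_normal(n_sets)
    X = np.repeat(M, 2) + np.sqrt(v_w) * rng.standard_normal(2 * n_sets)
    eta = X * beta
    for i in range(n_sets):
        sl = slice(2 * i, 2 * i + 2)
        e = eta[sl]
        p = np.exp(e - e.max())
        p /= p.sum()
        if rng.choice(2, p=p) != 0:
            X[sl] = X[sl][::-1]
    W = X + np.sqrt(sigma2) * rng.standard_normal(2 * n_sets)
    study = mm.MatchedStudy(
        set_ids=[f"s{i}" for i in range(n_sets)],
        sizes=np.full(n_sets, 2),
        W=W[:, None],
        Z=np.zeros((2 * n_sets, 0)),
    )
    truth = dict(v_w=v_w, v_b=v_b, sigma2=sigma2, mu=mu, beta=beta)
    return study, truth


@pytest.fixture(scope="session")
def pair_study():
    return make_pair_study()


@pytest.fixture(scope="session")
def default_synth():
    """One default-scenario synthetic study shared across tests."""
    return mm.generate(seed=1234)


@pytest.fixture(scope="session")
def default_spec(default_synth):
    return mm.MeasurementErrorSpec(sigma2=default_synth.config.sigma2)


def short_config(n_iter=3000, n_burn=1000, n_chains=2, seed=0, **kw):
    return mm.SamplerConfig(
        n_iter=n_iter, n_burn=n_burn, n_chains=n_chains, base_seed=seed, **kw
    )
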