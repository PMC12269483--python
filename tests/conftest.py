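import numpy as np
import pytest

import discoate as d


@pytest.fixture(scope="session")
def small_dataset():
    """Scenario-I draw small enough for fast unit tests."""
    return d.generate(d.ScenarioSpec.canonical("I", K=6, n=150, p=12, seed=123))


@pytest.fixture(scope="session")
def shift_dataset():
    """Covariate-shift (heterogeneous AR decay) draw."""
    return d.generate(d.ScenarioSpec.canonical("II", K=6, n=150, p=12, seed=321))


@pytest.fixture(scope="session")
def fast_config():
    return d.FitConfig(n_lambda=8, lambda_min_ratio=0.05)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)


def identical_sites_dataset(K=6, n=200, p=10, seed=5):
    """K exact copies of one site; the degenerate no-heterogeneity corner."""
    base = d.generate(d.ScenarioSpec.canonical("I", K=3, n=n, p=p, seed=seed))
    s0 = base.sites[0]
    sites = [d.SiteData(k + 1, s0._T.copy(), s0._Y.copy(), s0._X.copy())
             for k in range(K)]
    spec = d.ScenarioSpec.canonical("I", K=K, n=n, p=p, seed=seed)
    return d.MultiSiteDataset(sites=sites, spec=spec, true_tau1=2.0,
                              true_tau0=1.0, true_delta=1.0)
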