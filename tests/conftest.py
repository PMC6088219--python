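import numpy as np
import pandas as pd
import pytest

from latentq.qsem import McmcSettings, QSemSpec, gibbs_fit
from latentq.synthetic import (
    PERSONAL_DOMAINS,
    PSYCH_INDICATORS,
    SOCIOECONOMIC_DOMAINS,
    default_truth,
    generate_dataset,
)


@pytest.fixture(scope="session")
def truth_small():
    return default_truth(n=800, seed=424, error_family="ald")


@pytest.fixture(scope="session")
def data_small(truth_small):
    return generate_dataset(truth_small)


@pytest.fixture(scope="session")
def latent_spec(truth_small):
    return QSemSpec(
        eta_indicators=PSYCH_INDICATORS,
        xi1_indicators=SOCIOECONOMIC_DOMAINS,
        xi2_indicators=PERSONAL_DOMAINS,
        covariates=list(truth_small.covariate_names),
    )


@pytest.fixture(scope="session")
def median_fit(data_small, latent_spec):
    """A moderately long tau = 0.5 fit shared across tests."""
    ind, cov, _ = data_small
    mcmc = McmcSettings(chains=2, iterations=1600, burn_in=600, seed=99)
    return gibbs_fit(ind, cov, latent_spec, 0.5, mcmc)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def observed_qr_data():
    """Observed-response quantile-regression design (degenerate model)."""
    rng = np.random.default_rng(3)
    n = 200
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    xi1, xi2 = rng.normal(size=n), rng.normal(size=n)
    y = 1.0 + 0.5 * xi1 + 1.2 * xi2 + 0.8 * x1 - 0.4 * x2 + 0.8 * rng.normal(size=n)
    ind = pd.DataFrame({"eta_obs": y, "xi1_obs": xi1, "xi2_obs": xi2})
    cov = pd.DataFrame({"const": np.ones(n), "x1": x1, "x2": x2})
    design = np.column_stack([xi1, xi2, np.ones(n), x1, x2])
    return ind, cov, design, y
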