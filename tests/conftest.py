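import warnings

import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from raremeta import bayes_betabinom, bayes_logit, bundled_dataset, freq_meta


@pytest.fixture(scope="session")
def bundled():
    return bundled_dataset()


@pytest.fixture(scope="session")
def effects(bundled):
    return freq_meta.transform_table(bundled)


@pytest.fixture(scope="session")
def eb_fit(bundled):
    return bayes_betabinom.fit_empirical_bayes(bundled)


@pytest.fixture(scope="session")
def paper_fit():
    """Fit object wrapping the hyperparameters reported for this dataset."""
    return bayes_betabinom.BetaBinomFit.from_hyperparameters(16.48, 889.29)


@pytest.fixture(scope="session")
def posterior(bundled):
    """One default-spec MCMC fit of the bundled table, shared across tests."""
    return bayes_logit.sample_posterior(bundled, bayes_logit.LogitModelSpec(seed=0))
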