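import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from pharmirt import ModelConfig, fit, load_registry, paperlike_scenario


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def infra_fit():
    """One survey-scale infrastructure fit with known truth, shared across tests.

    Moderate chain: 1000 retained draws from 11k iterations, enough for the
    qualitative recovery and summary checks that reuse it.
    """
    matrix, truth = paperlike_scenario("infrastructure", seed=101)
    config = ModelConfig(
        anchor_item="5.05.03", n_burnin=1_000, n_iterations=11_000, thinning=10, seed=202
    )
    draws = fit(matrix, config)
    return matrix, truth, draws


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
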