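import numpy as np
import pytest

import strokesyn as ss


@pytest.fixture(scope="session")
def mini_config():
    """Small but complete cohort: 2 patients + 2 controls, 2 trials/block."""
    return ss.SimulationConfig(n_patients=2, n_controls=2, seed=42,
                               trials_per_block=2)


@pytest.fixture(scope="session")
def mini_cohort(mini_config):
    return ss.generate_cohort(mini_config)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
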