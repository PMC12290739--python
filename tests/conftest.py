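import numpy as np
import pytest

from pcmrsa import DesignParams, generate_design


@pytest.fixture(scope="session")
def design():
    """Default two-task design: 78 trials."""
    return generate_design(DesignParams())


@pytest.fixture(scope="session")
def paired_idx(design):
    return design.loc[design["block_type"] == "paired", "trial_index"].to_numpy()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
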