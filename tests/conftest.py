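import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_trajectory():
    """Small planted-epitope trajectory shared by the contact tests."""
    from oligobind.synthetic import gen_contact_trajectory

    return gen_contact_trajectory(seed=7, n_frames=120)
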