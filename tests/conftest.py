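import numpy as np
import pytest

from fmridesign import DesignSpec, canonical_hrf, generate_alternating_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def hrf_tr():
    """Canonical HRF sampled at the default TR of 1.5 s."""
    return canonical_hrf(dt=1.5)


@pytest.fixture
def default_spec():
    return DesignSpec(l_isi=2.0, u_isi=8.0, seed=7)


@pytest.fixture
def default_sequence(default_spec):
    return generate_alternating_sequence(default_spec)
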