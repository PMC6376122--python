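import numpy as np
import pytest

from erpfield.montage import (
    PERIPHERAL_BELT,
    apply_exclusion,
    build_montage,
    make_cap_montage,
)


@pytest.fixture(scope="session")
def full_montage():
    """Built-in 129-channel layout."""
    return build_montage()


@pytest.fixture(scope="session")
def study_montage(full_montage):
    """The analyzed 110-channel montage (peripheral belt excluded)."""
    return apply_exclusion(full_montage, PERIPHERAL_BELT)


@pytest.fixture(scope="session")
def small_montage():
    """A 16-channel cap for fast statistical tests."""
    return make_cap_montage(16)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
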