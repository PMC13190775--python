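import numpy as np
import pytest

from zoster_cea import basecase_fixture


@pytest.fixture(scope="session")
def basecase():
    """The shipped Swedish base-case parameter set (validated)."""
    return basecase_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20230915)
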