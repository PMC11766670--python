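import numpy as np
import pytest

from rnaevo import synthetic_data as sd


@pytest.fixture(scope="session")
def fixture_result():
    """The shipped 12-taxon mini-cohort (2 planted reversals, 1 planted CBC)."""
    return sd.fixture_suite()


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
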