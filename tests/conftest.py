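import numpy as np
import pytest

from classbsurvey import blosum62_scheme, default_registry
from classbsurvey.simulate import SimConfig, make_survey


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def scheme():
    # session-scoped: the aligner kernel is jitted on first use
    return blosum62_scheme()


@pytest.fixture(scope="session")
def survey():
    """One default synthetic survey shared by read-only tests."""
    return make_survey(SimConfig(seed=11))
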