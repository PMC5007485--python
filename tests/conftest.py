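import numpy as np
import pytest

from scn1a_dynamics import TrueChannelParams, load_condition
from scn1a_dynamics.synth import default_protocols


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


@pytest.fixture(scope="session")
def truth():
    """Default ground-truth channel (noiseless)."""
    return TrueChannelParams()


@pytest.fixture(scope="session")
def all_conditions():
    return {lab: load_condition(lab) for lab in ("WT37", "WT40", "AV37", "AV40")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160901)
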