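import pytest

from pgrass.olivar import ScreenPolicy, build_reference_model
from pgrass.restriction import digest


@pytest.fixture(scope="session")
def ref_model():
    """Seeded reference screening vector, shared across the suite."""
    return build_reference_model(1)


@pytest.fixture(scope="session")
def ref_fragment(ref_model):
    """The reference vector linearised at its unique SmaI site."""
    return digest(ref_model.seq)


@pytest.fixture(scope="session")
def policy():
    return ScreenPolicy()
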