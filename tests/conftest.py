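import pytest

from stromix.model import default_model


@pytest.fixture(scope="session")
def model():
    """The shipped 20-state model (copy numbers 0..7)."""
    return default_model()


@pytest.fixture(scope="session")
def emissions(model):
    return model.emissions()
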