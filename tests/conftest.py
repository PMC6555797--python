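import pytest

from s1drive import default_model


@pytest.fixture(scope="session")
def model():
    """The bundled S1 model: loci, killer/protector spec, named genotypes."""
    return default_model()


@pytest.fixture(scope="session")
def spec(model):
    return model.spec
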