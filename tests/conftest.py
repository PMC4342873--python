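import pytest

from pancore import build_matrix, reference_fixture


@pytest.fixture(scope="session")
def fixture():
    """The hand-checked 3-genome, 2-cluster worked example."""
    return reference_fixture()


@pytest.fixture(scope="session")
def toy_matrix(fixture):
    return build_matrix(fixture.omap)
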