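import pytest

from microtraits import synthetic


@pytest.fixture(scope="session")
def default_world():
    """One default synthetic chronosequence world, shared across tests."""
    return synthetic.generate_world(seed=7)


@pytest.fixture(scope="session")
def emitted_bundle(tmp_path_factory, default_world):
    """The default world's emitted file bundle."""
    out = tmp_path_factory.mktemp("bundle")
    paths = synthetic.emit_datasets(default_world, out)
    return default_world, paths
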