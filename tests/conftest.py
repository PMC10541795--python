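import pytest

from asecross.synthetic_data import SimConfig, write_fixture_bundle


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A small synthetic study written once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths = write_fixture_bundle(outdir, SimConfig(seed=11, n_genes=30))
    return paths
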