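import pytest

from clustrial.io import make_fixtures


@pytest.fixture(scope="session")
def fixtures(tmp_path_factory):
    """Deterministic fixture bundle (datasets, design YAML, mini study config)."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return make_fixtures(outdir, seed=0)
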