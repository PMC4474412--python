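import pytest

from shapemotif.simulate import FixtureSpec, make_fixture


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small planted-motif fixture, written to disk and shared read-only."""
    outdir = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(n_regions=300, seed=7)
    return make_fixture(spec, outdir=outdir)
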