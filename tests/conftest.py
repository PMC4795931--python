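import pytest

from genesetnet.fixtures import FixtureSpec, generate_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One shared synthetic input bundle with its ground-truth manifest."""
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = generate_bundle(FixtureSpec(seed=11), outdir)
    return outdir, manifest
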