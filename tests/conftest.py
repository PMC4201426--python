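import pytest

from invade.phylo import read_newick
from invade.synthetic import make_default_fixture


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the hand-computed example used throughout."""
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four_tree():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """A freshly generated copy of the bundled 77-species fixture set."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_default_fixture(outdir)
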