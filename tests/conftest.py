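import pytest

import cssn
from cssn import Signature


@pytest.fixture(scope="session")
def net():
    return cssn.load_bundled_network()


@pytest.fixture(scope="session")
def chem(net):
    return net.subtree("Chemical")


@pytest.fixture(scope="session")
def namer(net):
    return cssn.Namer(net)


@pytest.fixture(scope="session")
def sig(net):
    """Signature factory accepting ST names or TUIs."""

    def make(*sts):
        return Signature(net.resolve(s) for s in sts)

    return make


@pytest.fixture(scope="session")
def paper_index(net, chem):
    """Signature index over the published full-scale extent sizes."""
    pairs = cssn.iter_pairs(cssn.paper_extent_spec(), net)
    table = cssn.restrict_to_chemical(pairs, chem)
    return cssn.build_index(table)


@pytest.fixture(scope="session")
def small_index(net, chem):
    """Divisor-100 scaled version of the published extents, for fast builds."""
    pairs = cssn.iter_pairs(cssn.paper_extent_spec(divisor=100), net)
    table = cssn.restrict_to_chemical(pairs, chem)
    return cssn.build_index(table)


def index_for(seed, net, n_concepts=1000, **kwargs):
    """Random synthetic table -> restricted index, one call."""
    spec = cssn.random_spec(seed, n_concepts=n_concepts, net=net, **kwargs)
    pairs = cssn.iter_pairs(spec, net)
    table = cssn.restrict_to_chemical(pairs, net.subtree("Chemical"))
    return cssn.build_index(table)
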