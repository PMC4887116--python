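import pytest

from capsidsim.lattice import build_ccmv_lattice, build_toy_lattice
from capsidsim.ruleset import make_ruleset


@pytest.fixture(scope="session")
def ccmv_lattice():
    return build_ccmv_lattice()


@pytest.fixture(scope="session")
def triangle_lattice():
    return build_toy_lattice("triangle")


@pytest.fixture(scope="session")
def dodeca_lattice():
    return build_toy_lattice("dodecahedron")


@pytest.fixture(scope="session")
def triangle_ruleset():
    return make_ruleset("triangle", "uniform", kon=1.0e6, koff=2.0,
                        ring_closure_rate=30.0)


@pytest.fixture(scope="session")
def dodeca_ruleset():
    return make_ruleset("dodecahedron", "uniform", kon=2.0e5, koff=4.0,
                        ring_closure_rate=30.0)


@pytest.fixture(scope="session")
def ccmv_ruleset():
    return make_ruleset("ccmv", "nucleation")
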