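import pytest

from pathctrl import DirectedNetwork, SynthSpec, gen_pathway_collection


@pytest.fixture
def path_abc() -> DirectedNetwork:
    """Chain A->B->C: the middle node is the canonical control node."""
    return DirectedNetwork.from_edges([("A", "B"), ("B", "C")])


@pytest.fixture
def out_star() -> DirectedNetwork:
    """Hub h feeding three leaves: no control nodes at all."""
    return DirectedNetwork.from_edges([("h", "a"), ("h", "b"), ("h", "c")])


@pytest.fixture
def three_cycle() -> DirectedNetwork:
    return DirectedNetwork.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


@pytest.fixture(scope="session")
def crosstalk_collection():
    """A hub-rich synthetic collection shared by the slower analyses."""
    spec = SynthSpec(seed=3, n_shared_hubs=10)
    return gen_pathway_collection(spec)
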