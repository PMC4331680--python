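import pytest

from regmotifs import build_network


@pytest.fixture
def ffl_net():
    """The canonical coherent FFL: PI3K -> PDPK1 -> AKT3 with the direct
    PI3K -> AKT3 shortcut, all activating."""
    return build_network("ffl", [
        ("PI3K", "PDPK1", 1, "PPrel"),
        ("PDPK1", "AKT3", 1, "PPrel"),
        ("PI3K", "AKT3", 1, "PPrel"),
    ])


@pytest.fixture
def bifan_net():
    """EGF and TGFA both activating EGFR and ERBB2 (a 2x2 biclique with
    unconnected regulators)."""
    return build_network("bifan", [
        ("EGF", "EGFR", 1, "PPrel"),
        ("EGF", "ERBB2", 1, "PPrel"),
        ("TGFA", "EGFR", 1, "PPrel"),
        ("TGFA", "ERBB2", 1, "PPrel"),
    ])


@pytest.fixture
def path_graph():
    import networkx as nx
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def star_graph():
    import networkx as nx
    g = nx.Graph()
    g.add_edges_from([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])
    return g
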